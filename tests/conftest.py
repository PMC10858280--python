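import numpy as np
import pytest

from rarity.genotype_qc import GenotypeMatrix, VariantMeta


def make_matrix(dosages, chrom="1", positions=None, genes=None, state="raw",
                func=None, scores=None):
    """GenotypeMatrix from a plain array, with auto sample/variant ids."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    positions = positions if positions is not None else [1000 * (j + 1) for j in range(m)]
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    variants = []
    for j in range(m):
        variants.append(VariantMeta(
            chrom=chroms[j], pos=int(positions[j]), vid=f"v{j}",
            gene=None if genes is None else genes[j],
            func_class="other" if func is None else func[j],
            scores={} if scores is None else scores[j],
        ))
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(n)],
        variants=variants, dosages=dosages, state=state,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240209)
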