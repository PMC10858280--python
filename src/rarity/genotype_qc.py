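"""Genotype loading, variant-level quality control, and standardization.

The estimator downstream operates on an ``n`` samples x ``m`` variants
dosage matrix coded additively (0/1/2 copies of the minor allele) that has
been mean-imputed and column-standardized to mean 0 / variance 1.  This
module gets raw genotypes (VCF or a plain dosage TSV) into that state and
applies the variant filters appropriate for rare-variant analysis:
monomorphic removal, per-variant missingness, an exact Hardy-Weinberg test,
a minor-allele-count floor, and a minor-allele-frequency ceiling (optionally
enforced across reference-population frequencies as well).
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

FUNC_CLASSES = ("protein_altering", "lof", "other")

#: func_class values that qualify a variant as protein-altering for RV
#: analysis; loss-of-function variants always qualify.
PROTEIN_ALTERING = ("protein_altering", "lof")


@dataclass
class VariantMeta:
    """Per-variant annotation carried alongside one dosage column."""

    chrom: str
    pos: int
    vid: str
    ref: str = "A"
    alt: str = "C"
    maf_local: float | None = None
    mac: int | None = None
    maf_pops: dict = field(default_factory=dict)
    gene: str | None = None
    func_class: str = "other"
    scores: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"variant {self.vid}: pos must be >= 1, got {self.pos}")
        if self.maf_local is not None and not (0.0 <= self.maf_local <= 0.5):
            raise ValueError(f"variant {self.vid}: maf_local outside [0, 0.5]")
        if self.func_class not in FUNC_CLASSES:
            raise ValueError(
                f"variant {self.vid}: func_class must be one of {FUNC_CLASSES}"
            )

    @property
    def is_protein_altering(self) -> bool:
        return self.func_class in PROTEIN_ALTERING


@dataclass
class GenotypeMatrix:
    """Dosage matrix plus per-variant metadata and processing state.

    ``dosages`` is an ``n x m`` float array; missing genotypes are NaN while
    ``state`` is ``raw``.  After :func:`impute_and_standardize` every column
    has mean 0 and variance 1 (population denominator) and no missing
    entries.
    """

    samples: list
    variants: list
    dosages: np.ndarray
    state: str = "raw"

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError(f"{len(self.samples)} samples but {n} dosage rows")
        if m != len(self.variants):
            raise ValueError(f"{len(self.variants)} variants but {m} dosage columns")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants], dtype=object)

    def vids(self) -> list:
        return [v.vid for v in self.variants]

    def is_position_sorted(self) -> bool:
        """True when positions are non-decreasing within each chromosome."""
        prev: dict = {}
        for v in self.variants:
            if v.chrom in prev and v.pos < prev[v.chrom]:
                return False
            prev[v.chrom] = v.pos
        return True

    def sort_variants(self) -> "GenotypeMatrix":
        order = sorted(
            range(self.n_variants),
            key=lambda j: (self.variants[j].chrom, self.variants[j].pos,
                           self.variants[j].vid),
        )
        return self.subset(order)

    def subset(self, cols) -> "GenotypeMatrix":
        """New matrix restricted to the given column indices (order kept)."""
        cols = np.asarray(cols, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=[self.variants[j] for j in cols],
            dosages=self.dosages[:, cols].copy(),
            state=self.state,
        )

    def subset_samples(self, rows) -> "GenotypeMatrix":
        rows = np.asarray(rows, dtype=int)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            variants=list(self.variants),
            dosages=self.dosages[rows, :].copy(),
            state=self.state,
        )


@dataclass
class QcReport:
    """Counts of variants removed by each filter, in application order."""

    n_input: int = 0
    n_monomorphic_removed: int = 0
    n_missingness_removed: int = 0
    n_hwe_removed: int = 0
    n_mac_removed: int = 0
    n_maf_removed: int = 0
    n_retained: int = 0

    def removed_total(self) -> int:
        return (self.n_monomorphic_removed + self.n_missingness_removed
                + self.n_hwe_removed + self.n_mac_removed + self.n_maf_removed)

    def to_json(self, path=None) -> str:
        payload = json.dumps(dataclasses.asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def hwe_exact_p(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact two-sided Hardy-Weinberg test p-value.

    Enumerates the conditional distribution of the heterozygote count given
    the minor-allele count (Levene/Haldane null) with the usual stable
    recurrence, and sums the probabilities of all configurations no more
    likely than the observed one.  Suitable for rare variants where the
    chi-square approximation breaks down.
    """
    if min(n_het, n_hom_rare, n_hom_common) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    rare = 2 * n_hom_rare + n_het
    if rare > n:  # ensure 'rare' really is the minor allele
        rare = 2 * n - rare
    # heterozygote counts share the parity of the rare-allele count
    het_max = min(rare, 2 * n - rare)
    probs = np.zeros(het_max + 1)
    # start from the mode-ish midpoint with matching parity
    mid = int(rare * (2 * n - rare) / (2 * n))
    if mid % 2 != rare % 2:
        mid += 1
    mid = min(mid, het_max)
    probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / (4 (nr+1)(nc+1))
    h = mid
    while h >= 2:
        n_r = (rare - h) // 2
        n_c = n - n_r - h
        probs[h - 2] = probs[h] * h * (h - 1) / (4.0 * (n_r + 1) * (n_c + 1))
        h -= 2
    # upward recurrence: P(h+2)/P(h) = 4 nr nc / ((h+2)(h+1))
    h = mid
    while h + 2 <= het_max:
        n_r = (rare - h) // 2
        n_c = n - n_r - h
        probs[h + 2] = probs[h] * 4.0 * n_r * n_c / ((h + 2.0) * (h + 1.0))
        h += 2
    probs /= probs.sum()
    obs = min(n_het, het_max)
    p = probs[probs <= probs[obs] * (1.0 + 1e-12)].sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# loading


def _vcf_to_matrix(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    score_keys = {"CADD": "cadd", "MCAP": "mcap", "REVEL": "revel"}
    reader = VCF(str(path))
    samples = list(reader.samples)
    n = len(samples)
    cols = []
    metas = []
    for rec in reader:
        d = np.full(n, np.nan)
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                continue
            # multi-allelic records collapse to presence/absence of ANY
            # alternate allele: hom for one alt (1/1) scores 2, while a
            # compound het of two different alts (1/2) scores 1
            n_alt = sum(1 for a in alleles if a > 0)
            if n_alt == 2 and len(set(alleles)) > 1:
                n_alt = 1
            d[i] = n_alt
        info = dict(rec.INFO) if rec.INFO is not None else {}
        scores = {}
        for key, name in score_keys.items():
            if key in info:
                scores[name] = float(info[key])
        maf_pops = {
            k[4:].lower(): float(v) for k, v in info.items()
            if k.upper().startswith("MAF_")
        }
        func = str(info.get("FUNC", "other")).lower()
        if func not in FUNC_CLASSES:
            func = "other"
        alt = ",".join(rec.ALT) if rec.ALT else "."
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
        metas.append(VariantMeta(
            chrom=str(rec.CHROM), pos=int(rec.POS), vid=vid,
            ref=rec.REF or "N", alt=alt,
            gene=info.get("GENE"), func_class=func,
            scores=scores, maf_pops=maf_pops,
        ))
        cols.append(d)
    if not cols:
        raise ValueError(f"no variant records found in {path}")
    dosages = np.column_stack(cols)
    return GenotypeMatrix(samples=samples, variants=metas, dosages=dosages)


def read_variant_meta(path) -> dict:
    """Read a variant-metadata TSV keyed by vid.

    Recognized columns: vid, chrom, pos, ref, alt, gene, func_class,
    cadd, mcap, revel, plus any number of ``maf_<pop>`` columns.
    """
    import pandas as pd

    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA", ""])
    if "vid" not in tab.columns:
        raise ValueError(f"variant metadata {path} lacks a 'vid' column")
    out = {}
    maf_cols = [c for c in tab.columns if c.startswith("maf_")]
    for row in tab.itertuples(index=False):
        rec = row._asdict()
        scores = {k: (None if pd.isna(rec.get(k)) else float(rec[k]))
                  for k in ("cadd", "mcap", "revel") if k in rec}
        maf_pops = {c[4:]: float(rec[c]) for c in maf_cols if not pd.isna(rec[c])}
        gene = rec.get("gene")
        func = rec.get("func_class", "other")
        out[str(rec["vid"])] = VariantMeta(
            chrom=str(rec.get("chrom", "0")),
            pos=int(rec.get("pos", 1)),
            vid=str(rec["vid"]),
            ref=str(rec.get("ref", "A")),
            alt=str(rec.get("alt", "C")),
            gene=None if (gene is None or (isinstance(gene, float) and math.isnan(gene))) else str(gene),
            func_class="other" if (isinstance(func, float) and math.isnan(func)) else str(func),
            scores=scores,
            maf_pops=maf_pops,
        )
    return out


def _tsv_to_matrix(path, meta_path=None) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        fields = header.split("\t")
        vids = fields[1:]
        m = len(vids)
        samples = []
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != m + 1:
                raise ValueError(
                    f"{path}: line {lineno} (sample {parts[0] if parts else '?'}) "
                    f"has {len(parts) - 1} dosage fields, expected {m}"
                )
            samples.append(parts[0])
            rows.append([np.nan if x in ("NA", "") else float(x) for x in parts[1:]])
    dosages = np.array(rows, dtype=float)
    meta = {}
    if meta_path is None:
        base = os.fspath(path)
        stem = base[: base.rfind(".")] if "." in os.path.basename(base) else base
        candidates = [stem + ".variants.tsv"]
        if stem.endswith(".dosages"):
            candidates.append(stem[: -len(".dosages")] + ".variants.tsv")
        for candidate in candidates:
            if os.path.exists(candidate):
                meta_path = candidate
                break
    if meta_path is not None:
        meta = read_variant_meta(meta_path)
    variants = []
    for j, vid in enumerate(vids):
        if vid in meta:
            variants.append(meta[vid])
        else:
            chrom, pos = "0", j + 1
            parts = vid.split(":")
            if len(parts) >= 2 and parts[1].isdigit():
                chrom, pos = parts[0], int(parts[1])
            variants.append(VariantMeta(chrom=chrom, pos=pos, vid=vid))
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def load_genotypes(path, format: str | None = None, meta_path=None) -> GenotypeMatrix:
    """Load genotypes from VCF 4.x (plain or gzipped) or a dosage TSV.

    The TSV dialect is: tab-separated, header row of variant ids, one row
    per sample with the sample id in the first field, ``NA`` for missing.
    Variant metadata comes from a sidecar TSV (``<stem>.variants.tsv`` or
    ``meta_path``) keyed by vid.  Multi-allelic VCF records are collapsed to
    bi-allelic by counting the presence of any alternate allele.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        low = path.lower()
        format = "vcf" if (".vcf" in low or low.endswith(".bcf")) else "tsv"
    if format == "vcf":
        g = _vcf_to_matrix(path)
    elif format == "tsv":
        g = _tsv_to_matrix(path, meta_path=meta_path)
    else:
        raise ValueError(f"unknown genotype format {format!r} (vcf or tsv)")
    bad = ~(np.isnan(g.dosages) | np.isin(g.dosages, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"dosage for sample {g.samples[i]} / variant {g.variants[j].vid} "
            f"is {g.dosages[i, j]}, not in {{0,1,2,NA}}"
        )
    return g.sort_variants()


# ---------------------------------------------------------------------------
# filtering


def _column_stats(col: np.ndarray):
    obs = col[~np.isnan(col)]
    n_obs = obs.size
    miss_frac = 1.0 - n_obs / col.size
    if n_obs == 0:
        return n_obs, miss_frac, 0, 0.0, (0, 0, 0)
    alt = int(round(obs.sum()))
    mac = min(alt, 2 * n_obs - alt)
    maf = mac / (2.0 * n_obs)
    counts = np.bincount(obs.astype(int), minlength=3)
    n_het = int(counts[1])
    if alt <= n_obs:  # alt allele is the minor one
        hom_rare, hom_common = int(counts[2]), int(counts[0])
    else:
        hom_rare, hom_common = int(counts[0]), int(counts[2])
    return n_obs, miss_frac, mac, maf, (n_het, hom_rare, hom_common)


def qc_filter(
    g: GenotypeMatrix,
    missingness_max: float = 0.10,
    hwe_alpha: float = 5e-6,
    mac_min: int = 2,
    maf_max: float = 0.01,
    pop_maf_ceiling: bool = False,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the rare-variant filters and return the retained matrix.

    Filters are applied in a fixed order (monomorphic, missingness, exact
    HWE p < ``hwe_alpha``, MAC <= ``mac_min``, MAF >= ``maf_max``) and each
    variant is counted against the first filter it fails.  MAF/MAC are
    computed on observed (non-missing) calls; with ``pop_maf_ceiling`` the
    MAF ceiling additionally applies to every reference-population frequency
    in ``VariantMeta.maf_pops``.
    """
    if g.state != "raw":
        raise ValueError(f"qc_filter expects state='raw', got {g.state!r}")
    report = QcReport(n_input=g.n_variants)
    keep = []
    for j in range(g.n_variants):
        n_obs, miss_frac, mac, maf, hwe_counts = _column_stats(g.dosages[:, j])
        if n_obs == 0 or mac == 0:
            report.n_monomorphic_removed += 1
            continue
        if miss_frac > missingness_max:
            report.n_missingness_removed += 1
            continue
        if hwe_exact_p(*hwe_counts) < hwe_alpha:
            report.n_hwe_removed += 1
            continue
        if mac <= mac_min:
            report.n_mac_removed += 1
            continue
        pop_mafs = list(g.variants[j].maf_pops.values()) if pop_maf_ceiling else []
        if maf >= maf_max or any(p >= maf_max for p in pop_mafs):
            report.n_maf_removed += 1
            continue
        meta = dataclasses.replace(g.variants[j], maf_local=maf, mac=mac)
        keep.append((j, meta))
    report.n_retained = len(keep)
    out = g.subset([j for j, _ in keep])
    out.variants = [meta for _, meta in keep]
    return out, report


def impute_and_standardize(g: GenotypeMatrix) -> GenotypeMatrix:
    """Mean-impute missing dosages, then scale columns to mean 0 / var 1.

    Variance uses the population denominator ``n``, so the standardized
    matrix satisfies ``|mean| < 1e-8`` and ``|var - 1| < 1e-8`` per column.
    """
    if g.state != "raw":
        raise ValueError(f"impute_and_standardize expects state='raw', got {g.state!r}")
    X = g.dosages.copy()
    col_means = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_means[nan_c]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    zero = np.where(sd == 0)[0]
    if zero.size:
        raise ValueError(
            "zero-variance column(s) after imputation: "
            + ", ".join(g.variants[j].vid for j in zero[:5])
        )
    Z = (X - mu) / sd
    return GenotypeMatrix(
        samples=list(g.samples), variants=list(g.variants),
        dosages=Z, state="standardized",
    )
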