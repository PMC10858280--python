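"""Windowed pairwise-r² LD pruning.

Summing per-block variance explained over blocks double-counts signal
whenever variants in different blocks are correlated.  For rare coding
variants this correlation can extend over tens of megabases (long-range
LD), so the default regime is deliberately aggressive: r² > 0.1 inside a
50 Mb window.  Common-variant and combined presets use the conventional
relaxed regime (r² > 0.9, 1 Mb).

Two modes are provided: ``prune_first`` keeps the lower-position member of
a violating pair (deterministic positional greedy, the ordinary pruning
used before block construction) and ``clump_by_score`` keeps the
higher-scored member (used to retain the most pathogenic variant of each
correlated clique in enrichment analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .genotype_qc import GenotypeMatrix

MODES = ("prune_first", "clump_by_score")


@dataclass(frozen=True)
class PruneParams:
    r2_max: float
    window_bp: int
    step_bp: int = 500
    mode: str = "prune_first"

    def __post_init__(self):
        if not (0.0 < self.r2_max <= 1.0):
            raise ValueError(f"r2_max must be in (0, 1], got {self.r2_max}")
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must not exceed window_bp")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


_PRESETS = {
    # rare variants: stringent threshold over a very large window
    "rv_default": PruneParams(r2_max=0.1, window_bp=50_000_000, step_bp=500),
    # common variants and combined sets: conventional relaxed regime
    "cv_default": PruneParams(r2_max=0.9, window_bp=1_000_000, step_bp=500),
    "combined_default": PruneParams(r2_max=0.9, window_bp=1_000_000, step_bp=500),
}


def preset(name: str) -> PruneParams:
    """Named pruning-parameter presets (rv_default, cv_default, combined_default)."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(_PRESETS))}"
        ) from None


def prune(
    g: GenotypeMatrix,
    params: PruneParams,
    scores=None,
) -> tuple[GenotypeMatrix, list]:
    """Greedy windowed LD pruning; returns (pruned matrix, removed vids).

    After pruning, no retained pair on the same chromosome within
    ``window_bp`` has squared Pearson correlation above ``r2_max``.
    Candidates are visited in position order (``prune_first``; position
    ties broken by vid) or in descending score order (``clump_by_score``),
    and a candidate is dropped as soon as it violates the threshold
    against any already-retained variant in its window — a single greedy
    pass therefore satisfies the pairwise post-condition globally.
    Pruning never crosses chromosome boundaries.  The configured
    ``step_bp`` is carried for provenance; the pairwise distance check
    subsumes window stepping.
    """
    if g.state not in ("imputed", "standardized"):
        raise ValueError(
            f"prune expects an imputed or standardized matrix, got state={g.state!r}"
        )
    if not g.is_position_sorted():
        raise ValueError("variants must be position-sorted within each chromosome")
    if params.mode == "clump_by_score":
        if scores is None:
            raise ValueError("clump_by_score mode requires per-variant scores")
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (g.n_variants,):
            raise ValueError("scores must have one value per variant")

    X = g.dosages - g.dosages.mean(axis=0)
    norms = np.sqrt((X * X).sum(axis=0))
    norms[norms == 0] = np.inf  # constant columns correlate with nothing
    pos = g.positions()
    chroms = g.chroms()

    kept: list[int] = []
    removed: list[int] = []
    for chrom in dict.fromkeys(chroms):  # preserves first-appearance order
        idx = np.where(chroms == chrom)[0]
        if params.mode == "prune_first":
            order = sorted(idx, key=lambda j: (pos[j], g.variants[j].vid))
        else:
            order = sorted(idx, key=lambda j: (-scores[j], pos[j], g.variants[j].vid))
        retained: list[int] = []
        for j in order:
            ok = True
            for i in retained:
                if abs(pos[i] - pos[j]) > params.window_bp:
                    continue
                r = X[:, i] @ X[:, j] / (norms[i] * norms[j])
                if r * r > params.r2_max:
                    ok = False
                    break
            if ok:
                retained.append(j)
            else:
                removed.append(j)
        kept.extend(retained)

    kept.sort()
    removed_vids = [g.variants[j].vid for j in sorted(removed)]
    return g.subset(kept), removed_vids


def write_removed(removed_vids, path) -> None:
    """One removed vid per line (PLINK ``.prune.out`` convention)."""
    with open(path, "w") as fh:
        for vid in removed_vids:
            fh.write(f"{vid}\n")
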