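"""Genotype-block construction.

Heritability is estimated block by block and summed, so how columns are
grouped into regression designs matters.  Three constructs are supported:

* ``exome`` — runs of ~5000 adjacent pruned variants per chromosome,
  agnostic of gene borders (the headline construct);
* ``gene`` — one block per gene, all of its un-aggregated variants;
* ``burden`` — a single block whose predictors are per-gene burden scores
  (per-sample sums of rare-allele counts), quantifying the information
  lost by collapsing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_qc import GenotypeMatrix

log = logging.getLogger(__name__)

CONSTRUCTS = ("burden", "gene", "exome", "custom")


@dataclass
class Block:
    """One regression design: an ordered set of design-matrix columns."""

    kind: str
    columns: np.ndarray
    label: str

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=int)
        if self.columns.size < 1:
            raise ValueError(f"block {self.label}: must contain >= 1 column")

    @property
    def p_k(self) -> int:
        return int(self.columns.size)


@dataclass
class BlockSet:
    """Ordered blocks plus the design matrix their columns index into."""

    blocks: list
    construct: str
    design: np.ndarray
    samples: list = field(default_factory=list)
    labels: list = field(default_factory=list)  # per-column ids (vids or genes)

    def __post_init__(self):
        if self.construct not in CONSTRUCTS:
            raise ValueError(f"construct must be one of {CONSTRUCTS}")

    @property
    def K(self) -> int:
        return len(self.blocks)

    def total_predictors(self) -> int:
        return int(sum(b.p_k for b in self.blocks))

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "construct": self.construct,
                "blocks": [
                    {
                        "label": b.label,
                        "kind": b.kind,
                        "p_k": b.p_k,
                        "columns": [
                            self.labels[j] if self.labels else int(j)
                            for j in b.columns
                        ],
                    }
                    for b in self.blocks
                ],
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def _gene_labels(meta) -> list:
    """Gene labels for one variant; multi-gene annotations split on ';'."""
    if meta.gene is None:
        return []
    return [x for x in str(meta.gene).split(";") if x]


def make_exome_blocks(g: GenotypeMatrix, target_size: int = 5000) -> BlockSet:
    """Partition each chromosome into runs of ``target_size`` adjacent variants.

    A final remainder smaller than ``max(100, target_size // 10)`` is merged
    into its predecessor so no unstably small design is fitted.  Blocks
    never span chromosomes.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    if target_size >= g.n_samples:
        raise ValueError(
            f"target_size {target_size} >= n_samples {g.n_samples}; "
            "block designs must have many fewer predictors than samples"
        )
    if not g.is_position_sorted():
        raise ValueError("variants must be position-sorted within each chromosome")
    min_last = max(100, target_size // 10)
    chroms = g.chroms()
    blocks = []
    for chrom in dict.fromkeys(chroms):
        idx = np.where(chroms == chrom)[0]
        bounds = list(range(0, idx.size, target_size)) + [idx.size]
        if len(bounds) > 2 and bounds[-1] - bounds[-2] < min_last:
            bounds.pop(-2)  # merge remainder into its predecessor
        for j, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
            blocks.append(Block(kind="exome", columns=idx[a:b],
                                label=f"chr{chrom}_block{j}"))
    return BlockSet(blocks=blocks, construct="exome", design=g.dosages,
                    samples=list(g.samples), labels=g.vids())


def make_gene_blocks(g: GenotypeMatrix) -> BlockSet:
    """One block per distinct gene label, holding all of its variants.

    Variants without a gene annotation are excluded (count logged).  A
    variant annotated to several genes appears in each of their blocks; a
    gene whose variants sit on more than one chromosome stays one block
    (grouping is by gene label only) and is flagged in the log.
    """
    groups: dict[str, list[int]] = {}
    n_null = 0
    for j, meta in enumerate(g.variants):
        labels = _gene_labels(meta)
        if not labels:
            n_null += 1
            continue
        for lab in labels:
            groups.setdefault(lab, []).append(j)
    if n_null:
        log.warning("excluded %d variant(s) without a gene annotation", n_null)
    if not groups:
        raise ValueError("no variants carry a gene annotation")
    blocks = []
    for gene in sorted(groups):
        cols = np.array(groups[gene], dtype=int)
        n_chrom = len({g.variants[j].chrom for j in cols})
        if n_chrom > 1:
            log.warning("gene %s spans %d chromosomes; kept as one block",
                        gene, n_chrom)
        blocks.append(Block(kind="gene", columns=cols, label=gene))
    return BlockSet(blocks=blocks, construct="gene", design=g.dosages,
                    samples=list(g.samples), labels=g.vids())


def make_burden_block(g: GenotypeMatrix) -> tuple[BlockSet, np.ndarray]:
    """Collapse genes to burden scores and wrap them in a single block.

    Burden is the per-sample sum of raw (un-standardized) rare-allele
    counts over a gene's variants; burden columns are then standardized to
    mean 0 / variance 1.  Genes whose burden is constant (no carriers, or
    every sample an identical carrier pattern sum) are dropped with a log
    message.  Requires a raw or imputed matrix, since burden must be
    computed before genotype standardization.
    """
    if g.state == "standardized":
        raise ValueError(
            "burden scores must be computed from un-standardized dosages; "
            "pass the matrix before standardization"
        )
    groups: dict[str, list[int]] = {}
    for j, meta in enumerate(g.variants):
        for lab in _gene_labels(meta):
            groups.setdefault(lab, []).append(j)
    if not groups:
        raise ValueError("no variants carry a gene annotation")
    if len(groups) >= g.n_samples:
        raise ValueError(
            f"{len(groups)} genes >= {g.n_samples} samples; burden design not solvable"
        )
    X = g.dosages
    if np.isnan(X).any():
        col_means = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_means[None, :], X)
    genes = sorted(groups)
    burden = np.column_stack([X[:, groups[gene]].sum(axis=1) for gene in genes])
    sd = burden.std(axis=0)
    keep = sd > 0
    if (~keep).any():
        dropped = [gene for gene, k in zip(genes, keep) if not k]
        log.warning("dropped %d constant burden column(s): %s",
                    len(dropped), ", ".join(dropped[:5]))
    genes = [gene for gene, k in zip(genes, keep) if k]
    if not genes:
        raise ValueError("every gene burden column is constant")
    burden = burden[:, keep]
    burden = (burden - burden.mean(axis=0)) / burden.std(axis=0)
    block = Block(kind="burden", columns=np.arange(len(genes)), label="burden")
    bs = BlockSet(blocks=[block], construct="burden", design=burden,
                  samples=list(g.samples), labels=genes)
    return bs, burden
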