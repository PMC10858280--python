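"""Plain-text readers/writers for pipeline artifacts.

Dosage matrices travel as TSV (header of variant ids, one row per sample,
``NA`` for missing) with a sidecar variant-metadata TSV keyed by vid;
phenotype/covariate tables are TSV with a ``sample_id`` column; results are
written as per-block TSV plus JSON totals.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .genotype_qc import GenotypeMatrix
from .rarity_core import HeritabilityResult


def write_dosage_tsv(g: GenotypeMatrix, path, meta_path=None) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(g.vids()) + "\n")
        for i, sid in enumerate(g.samples):
            row = g.dosages[i]
            vals = "\t".join(
                "NA" if np.isnan(x) else (f"{x:g}" if g.state != "raw" else str(int(x)))
                for x in row
            )
            fh.write(f"{sid}\t{vals}\n")
    if meta_path is not None:
        write_variant_meta(g, meta_path)


def write_variant_meta(g: GenotypeMatrix, path) -> None:
    pops = sorted({p for v in g.variants for p in v.maf_pops})
    cols = ["vid", "chrom", "pos", "ref", "alt", "gene", "func_class",
            "cadd", "mcap", "revel"] + [f"maf_{p}" for p in pops]
    rows = []
    for v in g.variants:
        row = {
            "vid": v.vid, "chrom": v.chrom, "pos": v.pos,
            "ref": v.ref, "alt": v.alt,
            "gene": v.gene if v.gene is not None else "NA",
            "func_class": v.func_class,
        }
        for s in ("cadd", "mcap", "revel"):
            val = v.scores.get(s)
            row[s] = "NA" if val is None else val
        for p in pops:
            row[f"maf_{p}"] = v.maf_pops.get(p, "NA")
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_phenotype_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    if "sample_id" not in tab.columns:
        raise ValueError(f"{path}: phenotype table needs a 'sample_id' column")
    return tab.set_index("sample_id")


def write_result(result: HeritabilityResult, json_path=None, tsv_path=None,
                 extra: dict | None = None) -> dict:
    payload = result.to_dict()
    if extra:
        payload.update(extra)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    if tsv_path is not None:
        pd.DataFrame([
            {
                "label": e.label, "p_k": e.p_k, "r2": e.r2,
                "adj_r2": e.adj_r2, "var_adj_r2": e.var_adj_r2,
                "ci95_lo": e.ci95[0], "ci95_hi": e.ci95[1],
                "f_stat": e.f_stat, "p_value": e.p_value,
            }
            for e in result.blocks
        ]).to_csv(tsv_path, sep="\t", index=False)
    return payload
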