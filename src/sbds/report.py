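"""Oncoprint-style matrix export and cohort summaries.

The oncoprint is a driver-gene x specimen matrix. Each cell takes one of
five states derived from the maximal-depth insertion of that gene in
that specimen: none, sense_clonal, sense_subclonal, antisense_clonal,
antisense_subclonal (clonal = read depth strictly above the clonality
cutoff). Columns carry the specimen genotype and its normalized
insertion burden (NIB, min-max scaled across the cohort); rows carry the
orientation class of the driver. Rendering is out of scope — the export
is a data matrix (TSV + JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .clonality import ClonalityThreshold
from .driver_analysis import classify_orientation

__all__ = ["compute_nib", "OncoprintMatrix", "export_oncoprint"]

SCHEMA_VERSION = "1.0"

CELL_STATES = (
    "none",
    "sense_clonal",
    "sense_subclonal",
    "antisense_clonal",
    "antisense_subclonal",
)


def compute_nib(tables: dict[str, pd.DataFrame]) -> dict[str, float]:
    """Normalized insertion burden per specimen.

    NIB = (burden - min) / (max - min) over the cohort's per-specimen
    insertion counts; when all burdens are equal (including a
    single-specimen cohort) every NIB is defined as 1.0.
    """
    if not tables:
        raise ValueError("need at least one specimen")
    burdens = {sid: len(t) for sid, t in tables.items()}
    lo, hi = min(burdens.values()), max(burdens.values())
    if hi == lo:
        return {sid: 1.0 for sid in burdens}
    return {sid: (b - lo) / (hi - lo) for sid, b in burdens.items()}


@dataclass
class OncoprintMatrix:
    """Driver x specimen cell-state matrix with row/column annotations."""

    cells: pd.DataFrame  # rows: gene_id, columns: specimen_id, values in CELL_STATES
    nib: dict[str, float]
    genotypes: dict[str, str]
    orientation_class: dict[str, str]
    occurrence: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        out = self.cells.copy()
        out.insert(0, "orientation_class", [
            self.orientation_class.get(g, "indeterminate") for g in out.index
        ])
        out.insert(1, "occurrence", [self.occurrence.get(g, 0) for g in out.index])
        header = pd.DataFrame(
            [
                ["genotype", "", *[self.genotypes.get(s, "") for s in self.cells.columns]],
                ["NIB", "", *[f"{self.nib.get(s, float('nan')):.6g}" for s in self.cells.columns]],
            ],
            columns=["orientation_class", "occurrence", *self.cells.columns],
        )
        with open(path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(out.columns) + "\n")
            for _, row in header.iterrows():
                fh.write("#" + "\t".join(str(v) for v in row) + "\n")
            out.to_csv(fh, sep="\t", header=False)

    def to_json(self, path: str | Path | None = None) -> dict:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "genes": list(self.cells.index),
            "specimens": list(self.cells.columns),
            "cells": self.cells.values.tolist(),
            "nib": self.nib,
            "genotypes": self.genotypes,
            "orientation_class": self.orientation_class,
            "occurrence": self.occurrence,
        }
        if path is not None:
            Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
        return payload

    @classmethod
    def from_json(cls, payload: dict) -> "OncoprintMatrix":
        cells = pd.DataFrame(
            payload["cells"],
            index=pd.Index(payload["genes"], name="gene_id"),
            columns=payload["specimens"],
        )
        return cls(
            cells,
            dict(payload["nib"]),
            dict(payload["genotypes"]),
            dict(payload["orientation_class"]),
            dict(payload["occurrence"]),
        )


def export_oncoprint(
    drivers: pd.DataFrame,
    annotated: pd.DataFrame,
    threshold: ClonalityThreshold | int,
    genotypes: dict[str, str] | None = None,
    specimens: list[str] | None = None,
    min_sites: int = 3,
) -> OncoprintMatrix:
    """Build the oncoprint for the significant drivers.

    Rows are significant driver genes ordered by occurrence (number of
    specimens with any insertion in the gene) descending, ties by
    adjusted p ascending then gene id. Columns are specimens ordered by
    genotype label then NIB descending. Cell state comes from the
    maximal-depth insertion of the gene in the specimen. Raises when a
    driver gene never appears in the annotation.
    """
    cutoff = (
        threshold.cutoff_reads
        if isinstance(threshold, ClonalityThreshold)
        else int(threshold)
    )
    sig = drivers[drivers["significant"]] if "significant" in drivers else drivers
    gene_ids = list(sig["gene_id"])
    genic = annotated[annotated["gene_id"].notna()]
    known = set(genic["gene_id"])
    for g in gene_ids:
        if g not in known:
            raise ValueError(f"driver gene {g!r} absent from annotation")

    if specimens is None:
        specimens = sorted(annotated["specimen_id"].unique())
    genotypes = genotypes or {s: "" for s in specimens}
    per_spec = {
        s: annotated[annotated["specimen_id"] == s] for s in specimens
    }
    nib = compute_nib(per_spec)

    occurrence = {
        g: int(
            genic.loc[genic["gene_id"] == g, "specimen_id"].nunique()
        )
        for g in gene_ids
    }
    adj = dict(zip(sig["gene_id"], sig.get("adj_p", pd.Series(dtype=float))))
    gene_order = sorted(
        gene_ids, key=lambda g: (-occurrence[g], adj.get(g, 1.0), g)
    )
    spec_order = sorted(
        specimens, key=lambda s: (genotypes.get(s, ""), -nib[s], s)
    )

    cells = pd.DataFrame(
        "none",
        index=pd.Index(gene_order, name="gene_id"),
        columns=spec_order,
    )
    for g in gene_order:
        rows = genic[genic["gene_id"] == g]
        for s, group in rows.groupby("specimen_id"):
            if s not in cells.columns:
                continue
            top = group.loc[group["read_count"].idxmax()]
            orient = "sense" if top["relative_orientation"] == "sense" else "antisense"
            clon = "clonal" if top["read_count"] > cutoff else "subclonal"
            cells.loc[g, s] = f"{orient}_{clon}"

    orientation = {
        g: classify_orientation(genic[genic["gene_id"] == g], min_sites=min_sites)
        for g in gene_order
    }
    return OncoprintMatrix(cells, nib, genotypes, orientation, occurrence)
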