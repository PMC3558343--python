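"""From significant probes to genomic regions, and their annotation status.

Significant-probe masks (one per chromosome x strand signal) are turned into
maximal runs, merged across short insignificant gaps, and filtered by a
minimum probe count. The resulting intervals can be mapped against a gene
annotation (to list transcriptionally affected genes by overlap fraction) or
inverted against it (to extract unannotated transcribed regions, candidate
novel transcriptional units).

Coordinates are 0-based half-open internally and in BED output; GFF3 output
is 1-based closed. Strands are never merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import DataError

__all__ = [
    "ProbeAnnotation",
    "RegionSet",
    "call_regions",
    "map_to_annotation",
    "unannotated_regions",
    "read_gff3_genes",
    "read_probe_bed",
]

GENE_COLUMNS = ["gene_id", "chromosome", "start", "end", "strand"]


@dataclass
class ProbeAnnotation:
    """Genomic layout of the probes of one chromosome x strand signal."""

    chromosome: str
    strand: str
    starts: np.ndarray
    probe_length: int = 25

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        if self.strand not in ("+", "-"):
            raise DataError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.probe_length < 1:
            raise DataError("probe length must be >= 1 bp")
        if self.starts.size and np.any(np.diff(self.starts) <= 0):
            raise DataError(
                f"probe starts must be strictly increasing on {self.chromosome}{self.strand}"
            )

    @property
    def n_probes(self) -> int:
        return self.starts.size

    @property
    def median_spacing(self) -> float:
        if self.n_probes < 2:
            return float(self.probe_length)
        return float(np.median(np.diff(self.starts)))

    def to_bed(self, path, probe_ids=None) -> None:
        ids = probe_ids or [f"probe_{i}" for i in range(self.n_probes)]
        df = pd.DataFrame(
            {
                "chrom": self.chromosome,
                "start": self.starts,
                "end": self.starts + self.probe_length,
                "name": ids,
                "score": 0,
                "strand": self.strand,
            }
        )
        df.to_csv(path, sep="\t", header=False, index=False)


def read_probe_bed(path) -> dict[tuple[str, str], tuple[ProbeAnnotation, np.ndarray, list[str]]]:
    """Read a probe BED6 into per-(chromosome, strand) annotations.

    Returns ``{(chrom, strand): (annotation, row_indices, probe_names)}`` where
    ``row_indices`` are the 0-based BED line numbers, used to subset the
    matching columns of an expression TSV.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
        dtype={"chrom": str, "name": str, "strand": str},
    )
    out = {}
    for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=True):
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        grp = grp.iloc[order]
        length = int((grp["end"] - grp["start"]).median())
        ann = ProbeAnnotation(chrom, strand, grp["start"].to_numpy(), probe_length=length)
        out[(chrom, strand)] = (ann, grp.index.to_numpy(), grp["name"].tolist())
    return out


@dataclass
class RegionSet:
    """Called genomic intervals with per-region summaries.

    ``table`` columns: chromosome, start, end, strand, n_probes, mean_effect,
    max_abs_effect, min_local_fdr.
    """

    table: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.table):
            t = self.table
            if np.any(t["end"].to_numpy() <= t["start"].to_numpy()):
                raise DataError("region end must exceed start")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def lengths(self) -> np.ndarray:
        return (self.table["end"] - self.table["start"]).to_numpy()

    def to_bed6(self, path) -> None:
        """Write BED6; score = -10 log10(min local FDR), capped at 1000."""
        t = self.table
        fdr = t["min_local_fdr"].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            score = np.minimum(-10.0 * np.log10(np.maximum(fdr, 1e-300)), 1000.0)
        score = np.where(np.isfinite(score), score, 1000.0)
        df = pd.DataFrame(
            {
                "chrom": t["chromosome"],
                "start": t["start"],
                "end": t["end"],
                "name": [f"{self.label or 'region'}_{i}" for i in range(len(t))],
                "score": np.round(score).astype(int),
                "strand": t["strand"],
            }
        )
        df.to_csv(path, sep="\t", header=False, index=False)

    def to_gff3(self, path, source: str = "tilewave") -> None:
        lines = ["##gff-version 3"]
        for i, row in self.table.reset_index(drop=True).iterrows():
            attrs = (
                f"ID={self.label or 'region'}_{i};n_probes={row.n_probes};"
                f"mean_effect={row.mean_effect:.4g};min_local_fdr={row.min_local_fdr:.4g}"
            )
            lines.append(
                "\t".join(
                    [
                        str(row.chromosome),
                        source,
                        "transcribed_region",
                        str(int(row.start) + 1),  # 1-based closed
                        str(int(row.end)),
                        ".",
                        str(row.strand),
                        ".",
                        attrs,
                    ]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "chromosome",
            "start",
            "end",
            "strand",
            "n_probes",
            "mean_effect",
            "max_abs_effect",
            "min_local_fdr",
        ]
    )


def call_regions(
    mask: np.ndarray,
    probes: ProbeAnnotation,
    min_probes: int = 4,
    max_gap_bp: Optional[int] = None,
    effect: Optional[np.ndarray] = None,
    local_fdr: Optional[np.ndarray] = None,
    label: str = "",
) -> RegionSet:
    """Convert a significant-probe mask into genomic intervals.

    Maximal runs of significant probes are merged across insignificant gaps of
    at most ``max_gap_bp`` (measured from the end of the last significant
    probe to the start of the next; default twice the median probe spacing),
    then runs carrying fewer than ``min_probes`` significant probes are
    dropped. A region spans from its first probe start to its last probe start
    plus the probe length.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.size != probes.n_probes:
        raise DataError(f"mask length {mask.size} != probe count {probes.n_probes}")
    if max_gap_bp is None:
        max_gap_bp = int(round(2 * probes.median_spacing))
    sig = np.nonzero(mask)[0]
    if sig.size == 0:
        return RegionSet(_empty_table(), label=label)

    starts = probes.starts
    plen = probes.probe_length
    groups: list[list[int]] = [[sig[0]]]
    for idx in sig[1:]:
        gap = starts[idx] - (starts[groups[-1][-1]] + plen)
        if gap <= max_gap_bp:
            groups[-1].append(idx)
        else:
            groups.append([idx])

    rows = []
    for grp in groups:
        if len(grp) < min_probes:
            continue
        members = np.asarray(grp)
        row = {
            "chromosome": probes.chromosome,
            "start": int(starts[members[0]]),
            "end": int(starts[members[-1]] + plen),
            "strand": probes.strand,
            "n_probes": len(grp),
            "mean_effect": float(np.mean(effect[members])) if effect is not None else math.nan,
            "max_abs_effect": float(np.max(np.abs(effect[members])))
            if effect is not None
            else math.nan,
            "min_local_fdr": float(np.min(local_fdr[members]))
            if local_fdr is not None
            else math.nan,
        }
        rows.append(row)
    table = pd.DataFrame(rows) if rows else _empty_table()
    return RegionSet(table, label=label)


def _as_gene_table(annotation: Union[pd.DataFrame, str, Path]) -> pd.DataFrame:
    if isinstance(annotation, (str, Path)):
        return read_gff3_genes(annotation)
    missing = [c for c in GENE_COLUMNS if c not in annotation.columns]
    if missing:
        raise DataError(f"annotation table lacks columns {missing}")
    return annotation


def read_gff3_genes(path) -> pd.DataFrame:
    """Extract gene intervals from a GFF3 file (0-based half-open output)."""
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # surface the offending line if gffutils reports it
        raise DataError(f"malformed GFF3 annotation {path}: {exc}") from exc
    rows = []
    types = set(db.featuretypes())
    use = "gene" if "gene" in types else None
    for feat in db.all_features(featuretype=use):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        rows.append(
            {
                "gene_id": gene_id,
                "chromosome": feat.seqid,
                "start": feat.start - 1,  # GFF3 is 1-based closed
                "end": feat.end,
                "strand": feat.strand,
            }
        )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def _region_trees(regions: RegionSet, stranded: bool) -> dict:
    trees: dict = {}
    for row in regions.table.itertuples():
        key = (row.chromosome, row.strand) if stranded else row.chromosome
        trees.setdefault(key, IntervalTree()).addi(row.start, row.end)
    return trees


def map_to_annotation(
    regions: RegionSet,
    annotation: Union[pd.DataFrame, str, Path],
    min_overlap_fraction: float = 0.15,
    stranded: bool = True,
) -> pd.DataFrame:
    """Map called regions onto gene annotation by overlap fraction.

    For every gene the overlapped basepairs (regions are non-overlapping
    within a track, so overlaps add) are divided by the gene length; genes
    with a fraction >= ``min_overlap_fraction`` (default 15 %) are flagged as
    transcriptionally affected. Returns the per-gene hit table.
    """
    if not 0.0 < min_overlap_fraction <= 1.0:
        raise DataError(f"min_overlap_fraction must be in (0, 1], got {min_overlap_fraction}")
    genes = _as_gene_table(annotation)
    trees = _region_trees(regions, stranded)
    rows = []
    for g in genes.itertuples():
        key = (g.chromosome, g.strand) if stranded else g.chromosome
        tree = trees.get(key)
        overlap = 0
        if tree is not None:
            for iv in tree.overlap(g.start, g.end):
                overlap += min(iv.end, g.end) - max(iv.begin, g.start)
        length = g.end - g.start
        frac = overlap / length if length > 0 else 0.0
        rows.append(
            {
                "gene_id": g.gene_id,
                "chromosome": g.chromosome,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "gene_length": length,
                "overlap_bp": overlap,
                "overlap_fraction": frac,
                "retained": frac >= min_overlap_fraction,
            }
        )
    return pd.DataFrame(rows)


def unannotated_regions(
    regions: RegionSet,
    annotation: Union[pd.DataFrame, str, Path],
    min_length_bp: int = 200,
    exclusion_margin_bp: int = 500,
    stranded: bool = False,
) -> RegionSet:
    """Extract called regions away from any annotated gene.

    Keeps regions of at least ``min_length_bp`` with zero overlap with the
    annotation after padding every gene by ``exclusion_margin_bp`` on both
    sides (the padding operationalizes "near a gene or its promoter"). By
    default annotation on either strand excludes a region.
    """
    if min_length_bp < 1:
        raise DataError("min_length_bp must be >= 1")
    genes = _as_gene_table(annotation)
    trees: dict = {}
    for g in genes.itertuples():
        key = (g.chromosome, g.strand) if stranded else g.chromosome
        trees.setdefault(key, IntervalTree()).addi(
            max(g.start - exclusion_margin_bp, 0), g.end + exclusion_margin_bp
        )
    keep = []
    for i, row in enumerate(regions.table.itertuples()):
        if row.end - row.start < min_length_bp:
            continue
        key = (row.chromosome, row.strand) if stranded else row.chromosome
        tree = trees.get(key)
        if tree is not None and tree.overlap(row.start, row.end):
            continue
        keep.append(i)
    table = regions.table.iloc[keep].reset_index(drop=True)
    return RegionSet(table if len(keep) else _empty_table(), label=regions.label or "unannotated")
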