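"""Binary elements x factors occupancy matrix from ChIP peak catalogs.

Replicate peak sets for the same factor are merged (union of peaks, then
interval merge); factors with no occupancy over the element set or too few
peaks are dropped; the matrix entry is 1 iff the element overlaps >= 1 bp of
the factor's merged peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalSet, intersect_flags, merge_intervals, read_bed

MIN_PEAKS_DEFAULT = 50


@dataclass
class PeakDataset:
    dataset_id: str
    factor: str
    context: str
    peaks: IntervalSet
    qc_status: str = "unfiltered"

    def __post_init__(self) -> None:
        if not self.factor:
            raise ValueError("factor name must be non-empty")


@dataclass
class PeakSetCatalog:
    datasets: list[PeakDataset] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.datasets)

    def factors(self) -> list[str]:
        return [d.factor for d in self.datasets]


def read_catalog(manifest_path: str | Path, merge_contexts: bool = True) -> PeakSetCatalog:
    """Load a catalog from a manifest TSV (dataset_id, factor, context, path).

    Peak file paths are taken relative to the manifest's directory. With
    merge_contexts (default) the factor name alone keys replicate merging;
    otherwise 'factor@context' keeps cell contexts separate.
    """
    manifest_path = Path(manifest_path)
    tab = pd.read_csv(manifest_path, sep="\t")
    required = {"dataset_id", "factor", "context", "path"}
    if not required.issubset(tab.columns):
        raise ValueError(f"catalog manifest must have columns {sorted(required)}")
    base = manifest_path.parent
    datasets = []
    for r in tab.itertuples():
        factor = r.factor if merge_contexts else f"{r.factor}@{r.context}"
        datasets.append(
            PeakDataset(r.dataset_id, factor, r.context, read_bed(base / r.path))
        )
    return PeakSetCatalog(datasets)


def merge_replicates(catalog: PeakSetCatalog) -> PeakSetCatalog:
    """One dataset per factor name: the merged union of its replicates' peaks."""
    by_factor: dict[str, list[PeakDataset]] = {}
    for d in catalog.datasets:
        by_factor.setdefault(d.factor, []).append(d)
    merged = []
    for factor, group in by_factor.items():
        union = [iv for d in group for iv in d.peaks]
        merged.append(
            PeakDataset(
                dataset_id=factor,
                factor=factor,
                context=";".join(sorted({d.context for d in group})),
                peaks=merge_intervals(IntervalSet(union)),
                qc_status="merged",
            )
        )
    return PeakSetCatalog(merged)


def qc_filter(
    catalog: PeakSetCatalog,
    elements: IntervalSet,
    min_peaks: int = MIN_PEAKS_DEFAULT,
) -> tuple[PeakSetCatalog, dict]:
    """Drop factors with zero occupancy over the elements or < min_peaks peaks."""
    kept, dropped = [], []
    for d in catalog.datasets:
        if len(d.peaks) < min_peaks:
            dropped.append((d.factor, "too_few_peaks"))
            continue
        if not intersect_flags(elements, d.peaks).any():
            dropped.append((d.factor, "no_occupancy"))
            continue
        d.qc_status = "pass"
        kept.append(d)
    summary = {
        "input_factors": len(catalog),
        "retained_factors": len(kept),
        "dropped": dropped,
    }
    return PeakSetCatalog(kept), summary


def build_matrix(elements: IntervalSet, catalog: PeakSetCatalog) -> pd.DataFrame:
    """Elements x factors binary matrix (>= 1 bp overlap), column-sorted.

    Index is the element id; a sidecar of per-factor occupancy fractions is
    available via `occupancy_fractions`.
    """
    ids = elements.ids()
    if any(i is None for i in ids):
        raise ValueError("all elements must carry ids")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate element ids")
    cols = {}
    for d in sorted(catalog.datasets, key=lambda d: d.factor):
        cols[d.factor] = intersect_flags(elements, d.peaks).astype(np.uint8)
    matrix = pd.DataFrame(cols, index=pd.Index(ids, name="element_id"))
    return matrix


def occupancy_fractions(matrix: pd.DataFrame) -> pd.Series:
    """Per-factor fraction of elements occupied (column mean)."""
    return matrix.mean(axis=0).rename("occupancy_fraction")
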