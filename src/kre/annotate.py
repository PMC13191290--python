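"""Transcript classification and element-to-gene linking.

Elements are tied to stimulus-regulated transcripts by two routes: promoter
proximity (minimum gap between the element and the TSS point below 15 kb) and
long-range chromatin contacts whose bait overlaps the gene's promoter window
(TSS +/- 2 kb) and whose other end overlaps the element. Elements linked to
at least one regulated transcript form the positive (responsive) training
set; elements linked only to stimulus-insensitive transcripts form the
negative-control set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import ContactPair, GenomicInterval, IntervalSet, build_trees

PROMOTER_HALF_WIDTH = 2_000
MAX_LINK_DISTANCE = 15_000


@dataclass(frozen=True)
class PromoterWindow:
    gene: str
    chrom: str
    tss: int
    strand: str

    @property
    def window(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, max(0, self.tss - PROMOTER_HALF_WIDTH),
                               self.tss + PROMOTER_HALF_WIDTH)


def read_tss_table(path) -> list[PromoterWindow]:
    tab = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "position", "strand"}
    if not required.issubset(tab.columns):
        raise ValueError(f"TSS table must have columns {sorted(required)}")
    return [
        PromoterWindow(r.gene, r.chrom, int(r.position), r.strand)
        for r in tab.itertuples()
    ]


def classify_transcripts(de: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene class from one DE contrast.

    padj < alpha with positive log2FC -> activated, negative -> repressed,
    otherwise insensitive. The fold-change sign is a direction annotation,
    not a filter: repressed transcripts stay in play downstream.
    """
    if de["gene"].duplicated().any():
        dupes = de.loc[de["gene"].duplicated(), "gene"].unique()[:5]
        raise ValueError(f"duplicate gene rows in DE table: {list(dupes)}")
    sig = de["padj"].to_numpy() < alpha
    lfc = de["log2fc"].to_numpy()
    cls = np.where(sig & (lfc > 0), "activated",
                   np.where(sig & (lfc < 0), "repressed", "insensitive"))
    return pd.DataFrame({"gene": de["gene"].to_numpy(), "class": cls})


def classify_transcripts_egr1(
    de_ctrl: pd.DataFrame,
    de_pert: pd.DataFrame,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """EGR1 class per regulated gene from the two genotype contrasts.

    A gene regulated in the control genotype is EGR1-sensitive when its
    stimulus response collapses without EGR1 induction:
    |log2FC_ctrl - log2FC_pert| >= log2(fc_threshold).
    """
    classes = classify_transcripts(de_ctrl, alpha=alpha)
    regulated = classes.loc[classes["class"] != "insensitive", "gene"]
    pert = de_pert.set_index("gene")
    missing = [g for g in regulated if g not in pert.index]
    if missing:
        raise ValueError(f"regulated genes missing from perturbed contrast: {missing[:10]}")
    ctrl = de_ctrl.set_index("gene")
    out = classes.set_index("gene")
    out["egr1_class"] = "not_applicable"
    delta = (ctrl.loc[regulated, "log2fc"] - pert.loc[regulated, "log2fc"]).abs()
    sens = delta >= np.log2(fc_threshold)
    out.loc[regulated, "egr1_class"] = np.where(sens, "sensitive", "insensitive")
    return out.reset_index()


def link_elements(
    elements: IntervalSet,
    promoters: list[PromoterWindow],
    contacts: list[ContactPair],
    max_distance: int = MAX_LINK_DISTANCE,
) -> pd.DataFrame:
    """All (element, gene) links by proximity or contact.

    An element may link to several genes; a pair satisfying both rules is
    recorded once with type 'contact' (the more specific evidence).
    Columns: element_id, gene, link_type, distance (proximal only).
    """
    rows: dict[tuple[str, str], dict] = {}
    # proximity: minimum gap between the element interval and the TSS point
    by_chrom: dict[str, list[PromoterWindow]] = {}
    for p in promoters:
        by_chrom.setdefault(p.chrom, []).append(p)
    for iv in elements:
        for p in by_chrom.get(iv.chrom, []):
            if iv.start <= p.tss < iv.end:
                gap = 0
            elif p.tss < iv.start:
                gap = iv.start - p.tss
            else:
                gap = p.tss - (iv.end - 1)
            if gap <= max_distance:
                rows[(iv.id, p.gene)] = {
                    "element_id": iv.id, "gene": p.gene,
                    "link_type": "proximal", "distance": gap,
                }
    # contacts: bait over the promoter window, other end over the element
    elem_trees = build_trees(elements)
    prom_trees = build_trees(
        IntervalSet([
            GenomicInterval(p.window.chrom, p.window.start, p.window.end, p.gene)
            for p in promoters
        ])
    )
    for pair in contacts:
        ptree = prom_trees.get(pair.bait.chrom)
        etree = elem_trees.get(pair.other.chrom)
        if ptree is None or etree is None:
            continue
        genes = [hit.data.id for hit in ptree.overlap(pair.bait.start, pair.bait.end)]
        hits = [hit.data for hit in etree.overlap(pair.other.start, pair.other.end)]
        for g in genes:
            for iv in hits:
                rows[(iv.id, g)] = {
                    "element_id": iv.id, "gene": g,
                    "link_type": "contact", "distance": np.nan,
                }
    out = pd.DataFrame(
        rows.values(), columns=["element_id", "gene", "link_type", "distance"]
    )
    return out.sort_values(["element_id", "gene"], ignore_index=True)


def label_elements(
    links: pd.DataFrame, transcript_classes: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Training labels per linked element, plus a filter-count summary.

    An element linked to >= 1 regulated transcript is positive (responsive)
    regardless of additional insensitive links; elements linked only to
    insensitive transcripts form the negative set. Elements linked to both
    activated and repressed transcripts are labelled 'responsive' (the
    classifier predicts responsiveness, not direction). Unlinked elements are
    the caller's concern: only linked elements appear here.
    """
    cls = transcript_classes.set_index("gene")["class"]
    missing = [g for g in links["gene"].unique() if g not in cls.index]
    if missing:
        raise ValueError(f"linked genes lack transcript classes: {missing[:10]}")
    merged = links.assign(gene_class=cls.loc[links["gene"]].to_numpy())
    egr1 = None
    if "egr1_class" in transcript_classes.columns:
        egr1 = transcript_classes.set_index("gene")["egr1_class"]
        merged["gene_egr1"] = egr1.loc[merged["gene"]].to_numpy()

    out_rows = []
    for eid, grp in merged.groupby("element_id", sort=True):
        kinds = set(grp["gene_class"])
        if kinds <= {"insensitive"}:
            label, positive = "insensitive", False
        elif kinds >= {"activated", "repressed"}:
            label, positive = "responsive", True
        elif "activated" in kinds:
            label, positive = "activated", True
        else:
            label, positive = "repressed", True
        row = {"element_id": eid, "label": label, "responsive": positive}
        if egr1 is not None:
            ek = set(grp.loc[grp["gene_class"] != "insensitive", "gene_egr1"])
            if not positive:
                row["egr1_class"] = "not_applicable"
            elif ek == {"sensitive"}:
                row["egr1_class"] = "sensitive"
            elif "sensitive" in ek:
                row["egr1_class"] = "mixed"
            else:
                row["egr1_class"] = "insensitive"
        out_rows.append(row)
    labels = pd.DataFrame(out_rows)
    summary = {
        "linked_elements": int(labels.shape[0]),
        "positive": int(labels["responsive"].sum()),
        "negative": int((~labels["responsive"]).sum()),
    }
    return labels, summary
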