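"""Composite cis-element activity score and cross-cell-type transfer.

Each element's score adds the natural-log odds ratios of its selected
predictive occupancy features to fixed annotation components: +2 for
accessibility in early erythroblasts (CFU-E/ProE), -1 for accessibility at
later stages (BasoE/PolyE/OrthoE) where Kit is downregulated, -1 for lacking
accessibility in any Kit-positive cell context, +/-1 for ABC activity, +/-1
for H3K27ac, and +1 for conservation (element-summary PhyloP > 1). The fixed
components alone span [-4, +5]; feature weights extend the upper range.
Elements with total >= 4.0 are flagged as the high-activity set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import IntervalSet, intersect_flags

HIGH_SCORE_THRESHOLD = 4.0
CONSERVATION_THRESHOLD = 1.0


@dataclass(frozen=True)
class ElementAnnotations:
    element_id: str
    early: bool                 # accessible in CFU-E / ProE
    late: bool                  # accessible in BasoE / PolyE / OrthoE
    kit_context: bool           # accessible in any Kit-positive cell context
    abc_active: bool
    h3k27ac: bool
    conservation: float
    present_features: frozenset[str] = frozenset()


def fixed_components(
    early: bool,
    late: bool,
    kit_context: bool,
    abc_active: bool,
    h3k27ac: bool,
    conserved: bool,
    kit_context_penalty: bool = True,
    conservation_bonus: bool = True,
) -> dict[str, float]:
    """The six flag-driven score components.

    The -1 for absent Kit-context accessibility and the +1 conservation bonus
    are switchable; both default on (they are what produces the analytic
    [-4, +5] fixed-component range).
    """
    return {
        "early": 2.0 if early else 0.0,
        "late": -1.0 if late else 0.0,
        "kit_context": (0.0 if kit_context else -1.0) if kit_context_penalty else 0.0,
        "abc": 1.0 if abc_active else -1.0,
        "h3k27ac": 1.0 if h3k27ac else -1.0,
        "conservation": (1.0 if conserved else 0.0) if conservation_bonus else 0.0,
    }


def score_element(
    ann: ElementAnnotations,
    weights: pd.DataFrame,
    kit_context_penalty: bool = True,
    conservation_bonus: bool = True,
) -> dict:
    """Score one element; returns the component breakdown plus the total.

    `weights` is the selected-feature table (feature, log_odds_ratio,
    selected); only selected features contribute, and every present selected
    feature must carry a weight.
    """
    sel = weights.loc[weights["selected"]].set_index("feature")["log_odds_ratio"]
    present_selected = [f for f in ann.present_features if f in sel.index]
    unknown = [
        f for f in ann.present_features
        if f not in set(weights["feature"])
    ]
    if unknown:
        raise ValueError(f"present features without weights: {sorted(unknown)[:10]}")
    conserved = ann.conservation > CONSERVATION_THRESHOLD
    comps = fixed_components(
        ann.early, ann.late, ann.kit_context, ann.abc_active, ann.h3k27ac,
        conserved, kit_context_penalty, conservation_bonus,
    )
    comps["feature_weights"] = float(sel.loc[present_selected].sum())
    total = float(sum(comps.values()))
    return {
        "element_id": ann.element_id,
        **comps,
        "total": total,
        "conserved": bool(conserved),
        "high": bool(total >= HIGH_SCORE_THRESHOLD),
    }


def score_all(
    annotations: pd.DataFrame,
    occupancy: pd.DataFrame,
    weights: pd.DataFrame,
    element_ids: list[str] | None = None,
    high_threshold: float = HIGH_SCORE_THRESHOLD,
    kit_context_penalty: bool = True,
    conservation_bonus: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Score every element; ranked descending by total (ties by element id).

    `annotations` columns: element_id, early, late, kit_context, abc,
    h3k27ac, conservation. Present features are read off the occupancy
    matrix rows.
    """
    ids = element_ids if element_ids is not None else list(annotations["element_id"])
    ann_idx = annotations.set_index("element_id")
    missing = [e for e in ids if e not in ann_idx.index]
    if missing:
        raise ValueError(f"missing annotation rows for elements: {missing[:10]}")
    rows = []
    occ_cols = np.array(occupancy.columns)
    for eid in ids:
        if eid in occupancy.index:
            present = frozenset(occ_cols[occupancy.loc[eid].to_numpy().astype(bool)])
        else:
            present = frozenset()
        r = ann_idx.loc[eid]
        ann = ElementAnnotations(
            element_id=eid,
            early=bool(r["early"]),
            late=bool(r["late"]),
            kit_context=bool(r["kit_context"]),
            abc_active=bool(r["abc"]),
            h3k27ac=bool(r["h3k27ac"]),
            conservation=float(r["conservation"]),
            present_features=present,
        )
        rec = score_element(ann, weights, kit_context_penalty, conservation_bonus)
        rec["high"] = bool(rec["total"] >= high_threshold)
        rows.append(rec)
    table = pd.DataFrame(rows).sort_values(
        by=["total", "element_id"], ascending=[False, True], ignore_index=True
    )
    high = table.loc[table["high"]]
    summary = {
        "n_elements": len(table),
        "n_high": int(table["high"].sum()),
        "high_conserved_fraction": (
            float(high["conserved"].mean()) if len(high) else float("nan")
        ),
        "score_min": float(table["total"].min()) if len(table) else float("nan"),
        "score_max": float(table["total"].max()) if len(table) else float("nan"),
    }
    return table, summary


def transfer_partition(
    kres: IntervalSet,
    other_accessible: IntervalSet,
    other_enhancers: IntervalSet,
) -> dict:
    """Partition elements by accessibility/enhancer status in another cell type.

    shared = elements overlapping the other cell type's accessible regions;
    unique = the complement (exported as the retraining control group);
    enhancer_overlap = elements overlapping its enhancer annotations.
    """
    acc = intersect_flags(kres, other_accessible)
    enh = intersect_flags(kres, other_enhancers)
    ivs = list(kres)
    n = len(ivs)
    shared = IntervalSet([iv for iv, f in zip(ivs, acc) if f])
    unique = IntervalSet([iv for iv, f in zip(ivs, acc) if not f])
    enhancer = IntervalSet([iv for iv, f in zip(ivs, enh) if f])
    return {
        "shared": shared,
        "unique": unique,
        "enhancer_overlap": enhancer,
        "n": n,
        "n_shared": len(shared),
        "n_unique": len(unique),
        "n_enhancer": len(enhancer),
        "shared_fraction": len(shared) / n if n else 0.0,
        "enhancer_fraction": len(enhancer) / n if n else 0.0,
    }
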