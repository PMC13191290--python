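"""Synthetic cohort generator with planted ground truth.

Emulates the full data structure of an SCF/Kit stimulation study in erythroid
precursors: accessible elements on a toy genome, per-factor ChIP peak files,
four-condition accessibility signal tables (two genotypes x stimulated/control,
two replicates each), stimulus differential-expression contrasts per genotype,
promoter-capture contact pairs, TSS annotations, per-element scoring
annotations, and a second-cell-type accessibility/enhancer overlay. Every
element, gene and occupancy feature carries known planted truth so each
downstream stage can be tested for exact recovery.

Design of the planted structure
-------------------------------
Genes are partitioned into stimulus-activated / repressed / insensitive
classes; elements inherit the class of their (single) linked gene, so the
element labelling stage has an exact truth. Among responsive genes a
configured fraction is EGR1-sensitive: their stimulus response (both in
accessibility and expression) is abolished in the EGR1-perturbed genotype.
Occupancy features are Bernoulli with class-conditional prevalences for the
planted columns and a shared background rate elsewhere; planted prevalences
imply known odds ratios that estimators must recover.

Signal noise is log-normal on intensities (Gaussian on the log2 scale), the
multiplicative noise model appropriate for normalized accessibility signal.
Per-sample sequencing-depth factors are log-normal too, except in the exact
noiseless limit (noise_sigma == 0) where they are pinned to 1 so planted fold
changes appear verbatim in the emitted tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import ContactPair, GenomicInterval, IntervalSet, write_bed, write_bedpe

CHROMS = ("chr1", "chr2", "chr3")
CHROM_LEN = 20_000_000
GENE_WINDOW = 60_000          # private window per gene in the proximal zone
PROXIMAL_ZONE_END = 14_000_000
DISTAL_ZONE_START = 14_050_000
DISTAL_SLOT = 2_000
ELEMENT_LEN = 400
# proximal element offsets from the TSS (element start = TSS + offset);
# all yield TSS gaps < 15 kb and pairwise element gaps >= 1 kb
PROXIMAL_OFFSETS = (-4_000, 5_000, -8_000, 9_000, -12_000, 13_000, -14_300, 14_000)

# per-element scoring-annotation rates, (responsive, insensitive)
ANNOTATION_RATES = {
    "early": (0.60, 0.35),
    "late": (0.25, 0.40),
    "kit_context": (0.90, 0.70),
    "abc": (0.60, 0.40),
    "h3k27ac": (0.70, 0.45),
    "conserved": (0.29, 0.20),
}


def _default_planted() -> list[tuple[int, float, float]]:
    return [(i, 0.60, 0.16) for i in range(12)]


def _default_egr1_planted() -> list[tuple[int, float, float]]:
    return [(i, 0.65, 0.12) for i in range(12, 24)]


@dataclass
class CohortConfig:
    """Parameters of the synthetic study; defaults are the study conditions."""

    n_elements: int = 3000
    n_genes: int = 600
    n_features: int = 286
    n_decoy_features: int = 4          # emitted with zero peaks; QC must drop them
    planted_features: list[tuple[int, float, float]] = field(
        default_factory=_default_planted
    )
    egr1_planted_features: list[tuple[int, float, float]] = field(
        default_factory=_default_egr1_planted
    )
    frac_activated: float = 0.12
    frac_repressed: float = 0.08       # responsive total 0.20 -> 1:4 imbalance
    signal_fc_activated: float = 3.0
    signal_fc_repressed: float = 1.0 / 3.0
    noise_sigma: float = 0.1           # SD of log2-scale replicate noise
    depth_sigma: float = 0.15          # SD of log2 per-sample depth factor
    egr1_sensitive_frac: float = 0.622
    contact_frac: float = 0.2
    background_occupancy: float = 0.25
    replicates: int = 2
    replicate_chip_frac: float = 0.05  # fraction of factors emitted as 2 ChIP reps
    baseline_log2_mean: float = 6.64   # median intensity ~100
    baseline_log2_sd: float = 0.8
    baseline_log2_clip: tuple[float, float] = (5.0, 10.0)
    transfer_accessible_frac: float = 0.55
    transfer_enhancer_frac: float = 0.314
    footprint_background: float = 0.30
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_activated": self.frac_activated,
            "frac_repressed": self.frac_repressed,
            "egr1_sensitive_frac": self.egr1_sensitive_frac,
            "contact_frac": self.contact_frac,
            "background_occupancy": self.background_occupancy,
            "transfer_accessible_frac": self.transfer_accessible_frac,
            "transfer_enhancer_frac": self.transfer_enhancer_frac,
            "replicate_chip_frac": self.replicate_chip_frac,
            "footprint_background": self.footprint_background,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_activated + self.frac_repressed >= 1.0:
            raise ValueError("activated + repressed fractions must be < 1")
        for idx, p1, p0 in self.planted_features + self.egr1_planted_features:
            if not (0.0 < p1 < 1.0 and 0.0 < p0 < 1.0):
                raise ValueError(f"planted prevalences must be in (0,1): {(idx, p1, p0)}")
            if idx >= self.n_features:
                raise ValueError(
                    f"planted feature index {idx} >= n_features {self.n_features}"
                )
        if self.n_elements < 1 or self.n_genes < 1 or self.n_features < 1:
            raise ValueError("counts must be positive")
        if self.n_genes > len(CHROMS) * (PROXIMAL_ZONE_END // GENE_WINDOW):
            raise ValueError("n_genes exceeds toy-genome capacity")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.signal_fc_activated <= 0 or self.signal_fc_repressed <= 0:
            raise ValueError("fold changes must be positive")
        if self.noise_sigma < 0 or self.depth_sigma < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class CohortTruth:
    """Planted ground truth: per-element classes, per-gene effects, per-feature
    odds ratios, and element->gene links."""

    elements: pd.DataFrame   # element_id, chrom, start, end, gene, link_type, class, egr1_class
    genes: pd.DataFrame      # gene, class, egr1_class, lfc_ctrl, lfc_pert, chrom, tss, strand
    features: pd.DataFrame   # feature, planted, prev_pos, prev_neg, true_log_or, footprint_scf
    occupancy: pd.DataFrame  # elements x features, uint8
    config: CohortConfig


def feature_names(config: CohortConfig) -> list[str]:
    names = [f"TF{i:03d}" for i in range(config.n_features)]
    names += [f"TFD{i:02d}" for i in range(config.n_decoy_features)]
    return names


# ---------------------------------------------------------------------------
# truth assembly


def _assign_gene_classes(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    n_act = int(round(config.frac_activated * n))
    n_rep = int(round(config.frac_repressed * n))
    classes = np.array(
        ["activated"] * n_act + ["repressed"] * n_rep
        + ["insensitive"] * (n - n_act - n_rep)
    )
    rng.shuffle(classes)
    egr1 = np.full(n, "not_applicable", dtype=object)
    resp_idx = np.flatnonzero(classes != "insensitive")
    n_sens = int(round(config.egr1_sensitive_frac * len(resp_idx)))
    sens = rng.permutation(resp_idx)[:n_sens]
    egr1[resp_idx] = "insensitive"
    egr1[sens] = "sensitive"
    width = max(3, len(str(n - 1)))
    genes = pd.DataFrame(
        {
            "gene": [f"g{i:0{width}d}" for i in range(n)],
            "class": classes,
            "egr1_class": egr1,
        }
    )
    genes["chrom"] = [CHROMS[i % len(CHROMS)] for i in range(n)]
    genes["tss"] = [(i // len(CHROMS)) * GENE_WINDOW + GENE_WINDOW // 2 for i in range(n)]
    genes["strand"] = ["+" if i % 2 == 0 else "-" for i in range(n)]
    return genes


def _place_elements(
    genes: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, list[ContactPair]]:
    """Assign each element a gene, a genomic position, and a link type.

    (1 - contact_frac) of elements sit within 15 kb of their gene's TSS;
    the rest are placed in a distal zone and receive an explicit contact pair.
    """
    n = config.n_elements
    width = max(4, len(str(n - 1)))
    gene_of = np.array([i % config.n_genes for i in range(n)])
    rows = []
    contacts: list[ContactPair] = []
    slot_used: dict[int, int] = {}                # gene index -> proximal slots used
    distal_next = {c: DISTAL_ZONE_START for c in CHROMS}
    for e in range(n):
        g = gene_of[e]
        chrom = genes.at[g, "chrom"]
        tss = int(genes.at[g, "tss"])
        used = slot_used.get(g, 0)
        want_contact = rng.random() < config.contact_frac
        if not want_contact and used < len(PROXIMAL_OFFSETS):
            start = tss + PROXIMAL_OFFSETS[used]
            slot_used[g] = used + 1
            link = "proximal"
        else:
            start = distal_next[chrom]
            distal_next[chrom] += DISTAL_SLOT
            if start + ELEMENT_LEN > CHROM_LEN:
                raise ValueError("distal zone exhausted; reduce n_elements")
            link = "contact"
            contacts.append(
                ContactPair(
                    bait=GenomicInterval(chrom, tss - 1000, tss + 1000),
                    other=GenomicInterval(chrom, start, start + ELEMENT_LEN),
                    score=float(np.round(5 + 10 * rng.random(), 3)),
                )
            )
        rows.append(
            {
                "element_id": f"e{e:0{width}d}",
                "chrom": chrom,
                "start": start,
                "end": start + ELEMENT_LEN,
                "gene": genes.at[g, "gene"],
                "link_type": link,
            }
        )
    elements = pd.DataFrame(rows)
    gene_class = genes.set_index("gene")
    elements["class"] = gene_class.loc[elements["gene"], "class"].to_numpy()
    elements["egr1_class"] = gene_class.loc[elements["gene"], "egr1_class"].to_numpy()
    return elements, contacts


# ---------------------------------------------------------------------------
# occupancy


def simulate_occupancy(
    elements: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the binary elements x features occupancy matrix.

    Planted columns are Bernoulli with class-conditional prevalence (keyed on
    stimulus responsiveness, or on EGR1 sensitivity for the EGR1-planted set);
    all other columns share the background rate. Decoy columns are all-zero.
    Returns (matrix, feature truth table).
    """
    names = feature_names(config)
    n = len(elements)
    responsive = (elements["class"] != "insensitive").to_numpy()
    egr1_sens = (elements["egr1_class"] == "sensitive").to_numpy()
    prev = np.full((n, len(names)), config.background_occupancy)
    planted_kind = {name: "none" for name in names}
    prev_pos = {name: config.background_occupancy for name in names}
    prev_neg = {name: config.background_occupancy for name in names}
    for idx, p1, p0 in config.planted_features:
        name = names[idx]
        prev[:, idx] = np.where(responsive, p1, p0)
        planted_kind[name] = "kit"
        prev_pos[name], prev_neg[name] = p1, p0
    for idx, p1, p0 in config.egr1_planted_features:
        name = names[idx]
        if planted_kind[name] != "none":
            raise ValueError(f"feature {name} planted twice")
        col = np.full(n, config.background_occupancy)
        col[responsive] = np.where(egr1_sens[responsive], p1, p0)
        prev[:, idx] = col
        planted_kind[name] = "egr1"
        prev_pos[name], prev_neg[name] = p1, p0
    for j in range(config.n_features, len(names)):   # decoys: never occupied
        prev[:, j] = 0.0
    matrix = (rng.random((n, len(names))) < prev).astype(np.uint8)
    matrix = pd.DataFrame(matrix, index=elements["element_id"].to_numpy(), columns=names)
    matrix.index.name = "element_id"

    footprint = {}
    for name in names:
        if planted_kind[name] != "none":
            footprint[name] = True
        else:
            footprint[name] = bool(rng.random() < config.footprint_background)
    feats = pd.DataFrame(
        {
            "feature": names,
            "planted": [planted_kind[n_] for n_ in names],
            "prev_pos": [prev_pos[n_] for n_ in names],
            "prev_neg": [prev_neg[n_] for n_ in names],
            "footprint_scf": [footprint[n_] for n_ in names],
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = lambda p: p / (1 - p)  # noqa: E731
        feats["true_log_or"] = np.where(
            feats["planted"] != "none",
            np.log(odds(feats["prev_pos"]) / np.where(feats["prev_neg"] > 0,
                                                      odds(feats["prev_neg"]), np.nan)),
            0.0,
        )
    return matrix, feats


def _emit_chip_beds(
    elements: pd.DataFrame,
    matrix: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
    outdir: Path,
) -> pd.DataFrame:
    """Write one (or two replicate) peak BEDs per factor; intersecting them
    with the element BED reproduces the matrix exactly.

    Peaks are the occupied element intervals jittered outward by < 300 bp,
    safely below the minimum inter-element gap (1 kb) so no peak can touch a
    neighbouring element.
    """
    chip = outdir / "chip"
    chip.mkdir(parents=True, exist_ok=True)
    contexts = ("K562", "HUDEP2", "ERY")
    catalog_rows = []
    coords = elements.set_index("element_id")
    for j, factor in enumerate(matrix.columns):
        occupied = matrix.index[matrix[factor].to_numpy().astype(bool)]
        peaks = []
        for eid in occupied:
            row = coords.loc[eid]
            pad_l = int(rng.integers(0, 300))
            pad_r = int(rng.integers(0, 300))
            peaks.append(
                GenomicInterval(row["chrom"], int(row["start"]) - pad_l,
                                int(row["end"]) + pad_r)
            )
        two_reps = len(peaks) >= 4 and rng.random() < config.replicate_chip_frac
        if two_reps:
            assign = rng.integers(0, 3, size=len(peaks))  # 0->rep1, 1->rep2, 2->both
            rep1 = [p for p, a in zip(peaks, assign) if a in (0, 2)]
            rep2 = [p for p, a in zip(peaks, assign) if a in (1, 2)]
            if not rep1 or not rep2:   # keep the union intact
                rep1, rep2 = peaks, peaks
            for r, plist in ((1, rep1), (2, rep2)):
                path = chip / f"{factor}_rep{r}.bed"
                write_bed(IntervalSet(plist).sort(), path)
                catalog_rows.append(
                    {"dataset_id": f"{factor}_rep{r}", "factor": factor,
                     "context": contexts[j % 3], "path": f"chip/{factor}_rep{r}.bed"}
                )
        else:
            path = chip / f"{factor}.bed"
            write_bed(IntervalSet(peaks).sort(), path)
            catalog_rows.append(
                {"dataset_id": factor, "factor": factor,
                 "context": contexts[j % 3], "path": f"chip/{factor}.bed"}
            )
    return pd.DataFrame(catalog_rows)


# ---------------------------------------------------------------------------
# signals and expression


def _condition_fc(cls: str, egr1: str, genotype: str, config: CohortConfig) -> float:
    """Planted stimulated/control fold change for one element in one genotype."""
    if cls == "insensitive":
        return 1.0
    fc = config.signal_fc_activated if cls == "activated" else config.signal_fc_repressed
    if genotype == "egr1kd" and egr1 == "sensitive":
        return 1.0
    return fc


def simulate_signals(
    elements: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-element signals for ctrl/egr1kd x pbs/scf x replicates.

    Column names follow 'genotype_condition_rep'. Baseline intensity is
    log-normal (clipped); stimulated conditions multiply it by the planted
    class fold change, omitted for EGR1-sensitive elements in the perturbed
    genotype. noise_sigma == 0 also pins depth factors to 1 (exact limit).
    """
    n = len(elements)
    lo, hi = config.baseline_log2_clip
    base = np.clip(
        rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n), lo, hi
    )
    baseline = 2.0 ** base
    samples = [
        (g, c, r)
        for g in ("ctrl", "egr1kd")
        for c in ("pbs", "scf")
        for r in range(1, config.replicates + 1)
    ]
    depth_sigma = config.depth_sigma if config.noise_sigma > 0 else 0.0
    depth = {s: 2.0 ** rng.normal(0.0, depth_sigma) for s in samples}
    out = {"element_id": elements["element_id"].to_numpy()}
    cls = elements["class"].to_numpy()
    egr1 = elements["egr1_class"].to_numpy()
    for g, c, r in samples:
        fc = np.ones(n)
        if c == "scf":
            fc = np.array(
                [_condition_fc(cls[i], egr1[i], g, config) for i in range(n)]
            )
        noise = 2.0 ** rng.normal(0.0, config.noise_sigma, size=n)
        out[f"{g}_{c}_{r}"] = baseline * fc * depth[(g, c, r)] * noise
    return pd.DataFrame(out)


def simulate_expression(
    genes: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two stimulus DE contrasts (control and EGR1-perturbed genotypes)."""
    n = len(genes)
    lfc_act = np.log2(config.signal_fc_activated)
    lfc_rep = np.log2(config.signal_fc_repressed)
    planted = np.where(
        genes["class"] == "activated", lfc_act,
        np.where(genes["class"] == "repressed", lfc_rep, 0.0),
    )
    sens = (genes["egr1_class"] == "sensitive").to_numpy()
    planted_pert = np.where(sens, 0.0, planted)

    def one(planted_lfc: np.ndarray, contrast: str) -> pd.DataFrame:
        lfc = planted_lfc + rng.normal(0.0, config.noise_sigma, size=n)
        regulated = planted_lfc != 0.0
        if config.noise_sigma == 0:
            padj = np.where(regulated, 1e-6, 1.0)
        else:
            padj = np.where(
                regulated,
                10.0 ** -rng.uniform(4, 10, size=n),
                rng.uniform(0.2, 1.0, size=n),
            )
        return pd.DataFrame(
            {"gene": genes["gene"], "log2fc": lfc, "padj": padj, "contrast": contrast}
        )

    return one(planted, "scf_vs_pbs_ctrl"), one(planted_pert, "scf_vs_pbs_egr1kd")


# ---------------------------------------------------------------------------
# annotations and transfer overlay


def simulate_annotations(
    elements: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(elements)
    responsive = (elements["class"] != "insensitive").to_numpy()
    ann = {"element_id": elements["element_id"].to_numpy()}
    for name, (p_resp, p_ins) in ANNOTATION_RATES.items():
        p = np.where(responsive, p_resp, p_ins)
        draw = rng.random(n) < p
        if name == "conserved":
            score = np.where(
                draw,
                rng.normal(2.0, 0.4, size=n),
                rng.normal(0.2, 0.3, size=n),
            )
            ann["conservation"] = np.round(score, 4)
        else:
            ann[name] = draw.astype(int)
    return pd.DataFrame(ann)


def simulate_transfer_sets(
    elements: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> tuple[IntervalSet, IntervalSet]:
    """Second-cell-type accessible regions and enhancer annotations.

    A configured fraction of elements is accessible in the other cell type;
    enhancers are a nested subset of those, mirroring how enhancer calls are a
    refinement of accessibility.
    """
    n = len(elements)
    n_acc = int(round(config.transfer_accessible_frac * n))
    n_enh = min(int(round(config.transfer_enhancer_frac * n)), n_acc)
    order = rng.permutation(n)
    acc_idx = np.sort(order[:n_acc])
    enh_idx = np.sort(order[:n_enh])

    def to_set(idx: np.ndarray, tag: str) -> IntervalSet:
        ivs = []
        for k, i in enumerate(idx):
            row = elements.iloc[i]
            pad = int(rng.integers(0, 200))
            ivs.append(
                GenomicInterval(
                    row["chrom"], int(row["start"]) - pad, int(row["end"]) + pad,
                    f"{tag}{k:05d}",
                )
            )
        return IntervalSet(ivs).sort()

    return to_set(acc_idx, "acc"), to_set(enh_idx, "enh")


# ---------------------------------------------------------------------------
# top level


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def simulate_cohort(config: CohortConfig, outdir: str | Path) -> CohortTruth:
    """Generate the full cohort on disk; returns the planted truth.

    Same config (including seed) reproduces byte-identical files; the manifest
    lists every output with its sha256 checksum.
    """
    config.validate()
    outdir = Path(outdir)
    rng = np.random.default_rng(config.seed)

    genes = _assign_gene_classes(config, rng)
    elements, contacts = _place_elements(genes, config, rng)
    matrix, feats = simulate_occupancy(elements, config, rng)
    signals = simulate_signals(elements, config, rng)
    de_ctrl, de_pert = simulate_expression(genes, config, rng)
    annotations = simulate_annotations(elements, config, rng)
    mep_acc, mep_enh = simulate_transfer_sets(elements, config, rng)

    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)

    element_set = IntervalSet(
        [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.element_id)
            for r in elements.itertuples()
        ]
    ).sort()
    write_bed(element_set, outdir / "elements.bed")
    write_bedpe(contacts, outdir / "contacts.bedpe")
    catalog = _emit_chip_beds(elements, matrix, config, rng, outdir)
    catalog.to_csv(outdir / "chip_manifest.tsv", sep="\t", index=False)

    fmt = dict(sep="\t", index=False, float_format="%.6g")
    signals.to_csv(outdir / "signals.tsv", **fmt)
    de_ctrl.to_csv(outdir / "de_ctrl.tsv", **fmt)
    de_pert.to_csv(outdir / "de_egr1kd.tsv", **fmt)
    genes[["gene", "chrom", "tss", "strand"]].rename(columns={"tss": "position"}).to_csv(
        outdir / "tss.tsv", sep="\t", index=False
    )
    annotations.to_csv(outdir / "annotations.tsv", **fmt)
    feats[["feature", "footprint_scf"]].to_csv(outdir / "features.tsv", sep="\t", index=False)
    matrix.to_csv(outdir / "occupancy_matrix.tsv", sep="\t")
    write_bed(mep_acc, outdir / "mep_accessible.bed")
    write_bed(mep_enh, outdir / "mep_enhancers.bed")

    elements.to_csv(outdir / "truth" / "elements.tsv", sep="\t", index=False)
    genes.to_csv(outdir / "truth" / "genes.tsv", **fmt)
    feats.to_csv(outdir / "truth" / "features.tsv", **fmt)

    names = sorted(
        str(p.relative_to(outdir))
        for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.tsv"
    )
    manifest = pd.DataFrame(
        {"path": names, "sha256": [_sha256(outdir / n) for n in names]}
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)

    return CohortTruth(
        elements=elements, genes=genes, features=feats, occupancy=matrix, config=config
    )
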