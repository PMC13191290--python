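"""Transcript classification and element-gene linking rules."""

import numpy as np
import pandas as pd
import pytest

from kre.annotate import (
    PromoterWindow,
    classify_transcripts,
    classify_transcripts_egr1,
    label_elements,
    link_elements,
)
from kre.intervals import ContactPair, GenomicInterval, IntervalSet, read_bed, read_bedpe


def de_table(rows, contrast="c"):
    return pd.DataFrame(rows, columns=["gene", "log2fc", "padj"]).assign(contrast=contrast)


class TestClassifyTranscripts:
    @pytest.mark.parametrize(
        "lfc, padj, expected",
        [
            (0.8, 0.01, "activated"),
            (-1.2, 0.001, "repressed"),
            (2.0, 0.20, "insensitive"),
        ],
    )
    def test_rule(self, lfc, padj, expected):
        out = classify_transcripts(de_table([("g1", lfc, padj)]))
        assert out.loc[0, "class"] == expected

    def test_duplicate_gene_rows_rejected(self):
        with pytest.raises(ValueError):
            classify_transcripts(de_table([("g1", 1, 0.01), ("g1", 2, 0.01)]))

    @pytest.mark.parametrize(
        "lfc_ctrl, lfc_pert, expected",
        [
            (1.6, 0.1, "sensitive"),     # delta >= log2(1.5)
            (1.6, 1.5, "insensitive"),   # delta ~ 0.09
        ],
    )
    def test_egr1_rule(self, lfc_ctrl, lfc_pert, expected):
        ctrl = de_table([("g1", lfc_ctrl, 0.01), ("g2", 0.0, 0.9)])
        pert = de_table([("g1", lfc_pert, 0.01), ("g2", 0.0, 0.9)])
        out = classify_transcripts_egr1(ctrl, pert).set_index("gene")
        assert out.loc["g1", "egr1_class"] == expected
        assert out.loc["g2", "egr1_class"] == "not_applicable"

    def test_regulated_gene_missing_from_perturbed_contrast(self):
        ctrl = de_table([("g1", 1.6, 0.01)])
        pert = de_table([("g2", 0.0, 0.9)])
        with pytest.raises(ValueError, match="g1"):
            classify_transcripts_egr1(ctrl, pert)

    def test_gene_classes_equal_truth_on_noiseless_cohort(self, noiseless_cohort):
        outdir, truth = noiseless_cohort
        out = classify_transcripts_egr1(
            pd.read_csv(outdir / "de_ctrl.tsv", sep="\t"),
            pd.read_csv(outdir / "de_egr1kd.tsv", sep="\t"),
        ).set_index("gene")
        expected = truth.genes.set_index("gene")
        assert (out.loc[expected.index, "class"] == expected["class"]).all()
        assert (
            out.loc[expected.index, "egr1_class"] == expected["egr1_class"]
        ).all()


def promoters_for(genes):
    return [PromoterWindow(g, c, t, "+") for g, c, t in genes]


class TestLinkElements:
    def test_proximal_link_within_15kb(self):
        elements = IntervalSet([GenomicInterval("chr1", 111_800, 112_200, "e1")])
        proms = promoters_for([("g1", "chr1", 100_000)])
        links = link_elements(elements, proms, [])
        assert len(links) == 1
        assert links.loc[0, "link_type"] == "proximal"
        assert links.loc[0, "distance"] == 11_800

    def test_distal_contact_link(self):
        elements = IntervalSet([GenomicInterval("chr1", 600_000, 600_400, "e1")])
        proms = promoters_for([("g1", "chr1", 100_000)])
        contact = ContactPair(
            GenomicInterval("chr1", 99_000, 101_000),
            GenomicInterval("chr1", 599_900, 600_500),
        )
        links = link_elements(elements, proms, [contact])
        assert links.loc[0, "link_type"] == "contact"

    def test_no_link_beyond_15kb_without_contact(self):
        elements = IntervalSet([GenomicInterval("chr1", 120_100, 120_500, "e1")])
        proms = promoters_for([("g1", "chr1", 100_000)])
        assert len(link_elements(elements, proms, [])) == 0

    def test_contact_preferred_when_both_rules_fire(self):
        elements = IntervalSet([GenomicInterval("chr1", 105_000, 105_400, "e1")])
        proms = promoters_for([("g1", "chr1", 100_000)])
        contact = ContactPair(
            GenomicInterval("chr1", 99_500, 100_500),
            GenomicInterval("chr1", 105_100, 105_200),
        )
        links = link_elements(elements, proms, [contact])
        assert len(links) == 1 and links.loc[0, "link_type"] == "contact"

    def test_raising_max_distance_only_adds_links(self, rng):
        elements = IntervalSet(
            [
                GenomicInterval("chr1", int(s), int(s) + 300, f"e{i}")
                for i, s in enumerate(sorted(rng.choice(10**6, 50, replace=False)))
            ]
        )
        proms = promoters_for(
            [(f"g{i}", "chr1", int(t)) for i, t in enumerate(rng.choice(10**6, 20, replace=False))]
        )
        small = link_elements(elements, proms, [], max_distance=10_000)
        big = link_elements(elements, proms, [], max_distance=25_000)
        small_pairs = set(map(tuple, small[["element_id", "gene"]].to_numpy()))
        big_pairs = set(map(tuple, big[["element_id", "gene"]].to_numpy()))
        assert small_pairs <= big_pairs

    def test_matches_brute_force_on_cohort(self, small_cohort):
        outdir, truth = small_cohort
        elements = read_bed(outdir / "elements.bed")
        tss = pd.read_csv(outdir / "tss.tsv", sep="\t")
        proms = [
            PromoterWindow(r.gene, r.chrom, int(r.position), r.strand)
            for r in tss.itertuples()
        ]
        contacts = read_bedpe(outdir / "contacts.bedpe")
        links = link_elements(elements, proms, contacts)
        got = set(map(tuple, links[["element_id", "gene"]].to_numpy()))
        # brute force over all (element, gene) pairs
        expected = set()
        for iv in elements:
            for p in proms:
                if iv.chrom != p.chrom:
                    continue
                gap = 0 if iv.start <= p.tss < iv.end else min(
                    abs(p.tss - iv.start), abs(p.tss - (iv.end - 1))
                )
                if gap <= 15_000:
                    expected.add((iv.id, p.gene))
        for pair in contacts:
            for p in proms:
                if p.chrom == pair.bait.chrom and (
                    max(0, p.tss - 2000) < pair.bait.end and pair.bait.start < p.tss + 2000
                ):
                    for iv in elements:
                        if (
                            iv.chrom == pair.other.chrom
                            and iv.start < pair.other.end
                            and pair.other.start < iv.end
                        ):
                            expected.add((iv.id, p.gene))
        assert got == expected
        # and the generator's own links are all recovered
        truth_pairs = set(map(tuple, truth.elements[["element_id", "gene"]].to_numpy()))
        assert truth_pairs <= got


class TestLabelElements:
    def _links(self, pairs):
        return pd.DataFrame(
            [
                {"element_id": e, "gene": g, "link_type": "proximal", "distance": 1}
                for e, g in pairs
            ]
        )

    def _classes(self, rows):
        return pd.DataFrame(rows, columns=["gene", "class"])

    def test_regulated_link_makes_positive(self):
        labels, _ = label_elements(
            self._links([("e1", "gA")]), self._classes([("gA", "activated")])
        )
        assert labels.loc[0, "responsive"]

    def test_only_insensitive_links_make_negative(self):
        labels, _ = label_elements(
            self._links([("e1", "gI")]), self._classes([("gI", "insensitive")])
        )
        assert not labels.loc[0, "responsive"]

    def test_conflict_rule_regulated_wins(self):
        labels, _ = label_elements(
            self._links([("e1", "gA"), ("e1", "gI")]),
            self._classes([("gA", "activated"), ("gI", "insensitive")]),
        )
        assert labels.loc[0, "responsive"] and labels.loc[0, "label"] == "activated"

    def test_both_directions_label_responsive(self):
        labels, _ = label_elements(
            self._links([("e1", "gA"), ("e1", "gR")]),
            self._classes([("gA", "activated"), ("gR", "repressed")]),
        )
        assert labels.loc[0, "label"] == "responsive"

    def test_every_element_in_exactly_one_set(self, small_cohort):
        outdir, truth = small_cohort
        links = self._links(
            list(map(tuple, truth.elements[["element_id", "gene"]].to_numpy()))
        )
        classes = truth.genes[["gene", "class"]]
        labels, summary = label_elements(links, classes)
        assert summary["positive"] + summary["negative"] == len(labels)
        assert labels["element_id"].is_unique

    def test_labels_equal_truth(self, noiseless_cohort):
        _, truth = noiseless_cohort
        links = self._links(
            list(map(tuple, truth.elements[["element_id", "gene"]].to_numpy()))
        )
        labels, _ = label_elements(links, truth.genes[["gene", "class", "egr1_class"]])
        expected = truth.elements.set_index("element_id")
        got = labels.set_index("element_id")
        assert (
            got["responsive"]
            == (expected.loc[got.index, "class"] != "insensitive")
        ).all()
        resp = got[got["responsive"]]
        assert (
            resp["egr1_class"] == expected.loc[resp.index, "egr1_class"]
        ).all()
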