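"""Score responsive elements and partition them against another cell type.

Adds selected-feature log-odds weights to the fixed annotation components
(early/late stage accessibility, Kit-context accessibility, ABC activity,
H3K27ac, conservation) for every responsive element, flags the high set
(total >= 4), then splits elements by accessibility and enhancer status in
the second cell type, exporting the unique set as the retraining control
group.
"""

from common import analysis_config

from kre.pipeline import stage_score, stage_transfer


def main() -> None:
    cfg = analysis_config()
    scores = stage_score(cfg)
    print(
        f"scored {scores['n_elements']} elements: {scores['n_high']} high, "
        f"range [{scores['score_min']:.2f}, {scores['score_max']:.2f}], "
        f"conserved fraction of high set {scores['high_conserved_fraction']:.2f}"
    )
    transfer = stage_transfer(cfg)
    print(
        f"transfer: {transfer['n_shared']}/{transfer['n']} "
        f"({100 * transfer['shared_fraction']:.1f}%) accessible in the other "
        f"cell type; {transfer['n_enhancer']}/{transfer['n']} "
        f"({100 * transfer['enhancer_fraction']:.1f}%) enhancer-annotated"
    )


if __name__ == "__main__":
    main()
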