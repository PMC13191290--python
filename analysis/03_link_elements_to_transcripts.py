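"""Link elements to stimulus-regulated transcripts and label them.

Classifies transcripts from the two DE contrasts, links elements to gene
promoters by proximity (< 15 kb to the TSS) or by contact pairs whose bait
covers the promoter window, and labels each linked element: responsive
(positive training class) if any linked transcript is regulated, negative
control if linked only to insensitive transcripts.
"""

from common import analysis_config

from kre.pipeline import stage_annotate


def main() -> None:
    result = stage_annotate(analysis_config())
    print(
        f"linked {result['linked_elements']} elements: "
        f"{result['positive']} positive, {result['negative']} negative, "
        f"{result['unlinked_elements']} unlinked"
    )


if __name__ == "__main__":
    main()
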