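"""Generate the synthetic study cohort.

Emits, under results/pipeline/cohort/, the full data structure of an acute
stimulation experiment: 3000 accessible elements linked to 600 genes on a
toy genome, four-condition accessibility signals (two genotypes x
stimulated/control, two replicates), two stimulus DE contrasts, 286 ChIP
peak files plus 4 decoys, promoter contacts, TSS and scoring annotations,
and a second-cell-type accessibility overlay — all with planted truth
recorded under cohort/truth/.
"""

from common import analysis_config

from kre.pipeline import stage_simulate


def main() -> None:
    cfg = analysis_config()
    result = stage_simulate(cfg)
    print(f"simulated {result['n_elements']} elements into {cfg.workdir}/cohort")


if __name__ == "__main__":
    main()
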