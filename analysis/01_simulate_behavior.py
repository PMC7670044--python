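"""Simulate the recognition-memory cohort: design and responses.

Generates the 512-word pool, the counterbalanced 8-run test design
(16 once-studied + 16 thrice-studied + 32 new words per run, 4 null events,
2-6 s jittered ITIs), and a 14-subject response table drawn at the
calibrated per-condition response probabilities, with payoff-dependent
criterion shifts built into the cell probabilities. Writes the design and
responses as TSV under results/analysis/behavior/.
"""

from pathlib import Path

from plsmem.design import (DesignParams, SdtParams, generate_design,
                           generate_word_pool, simulate_cohort,
                           write_events_tsv)

OUT = Path("results/analysis/behavior")
SEED = 20


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = DesignParams(rng_seed=SEED)
    sdt = SdtParams(mode="rate")

    pool = generate_word_pool(params)
    design = generate_design(pool, params)
    write_events_tsv(design, OUT / "events_sub-01.tsv")

    responses = simulate_cohort(params, sdt, rng_seed=SEED)
    responses.to_csv(OUT / "responses.tsv", sep="\t", index=False)

    n_trials = len(responses) // params.n_subjects
    print(f"simulated {params.n_subjects} subjects, "
          f"{n_trials} scored trials each "
          f"({params.n_runs} runs x {params.words_per_run} words)")
    print(f"wrote {OUT/'responses.tsv'} and {OUT/'events_sub-01.tsv'}")


if __name__ == "__main__":
    main()
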