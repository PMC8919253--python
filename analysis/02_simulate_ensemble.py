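"""Simulate the 18-trajectory Coulomb-explosion ensemble and tabulate breaks.

Runs the full protocol — thermalize the protonated ion near 300 K, sample 18
starting configurations at least 1 ps apart, explode each at +3 for 1 ps at
a 0.5 fs step — then classifies bond breaking with the integrity parameter
and writes the break-probability table and fragment census under
results/ensemble/.
"""

from cexfrag.pipeline import PipelineConfig, run_pipeline


def main(seed: int = 2022) -> None:
    cfg = PipelineConfig(
        output_dir="results/ensemble",
        seed=seed,
        ensemble_size=18,
        save_stride=4,
        log_level="WARNING",
    )
    result = run_pipeline(cfg)
    table = result["break_table"]
    census = result["census"]
    print("Break probabilities over the 18-run ensemble (per-trajectory counting):")
    print(
        table[
            ["bond_class", "n_events", "probability_pct_rounded",
             "ci95_low_pct", "ci95_high_pct", "fragments"]
        ].to_string(index=False)
    )
    print("\nFragment census at the final frames (hypothetical +1 m/z):")
    print(census.to_string(index=False))
    broken_runs = sum(
        1 for _ in result["ensemble"]
    ) - int(census[census.nominal_mz_plus1 == 241]["count"].sum())
    print(
        f"\n{broken_runs} of {len(result['ensemble'])} trajectories ended with "
        "at least one broken bond; with only 18 samples the Wilson intervals "
        "above are wide — ensemble size, not the classifier, limits precision."
    )


if __name__ == "__main__":
    import sys

    main(int(sys.argv[1]) if len(sys.argv) > 1 else 2022)
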