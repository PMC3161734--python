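#!/usr/bin/env python
"""Carbon-yield distributions under night-time downregulation.

Runs the full scenario (G6P + acetate, six regulated enzymes) and writes
the per-target summary for the three schemes (all modes / complete
knockout / 10% weighting) to results/yield_summary_full.tsv, then prints
the headline: whether the mean yield rises while the maximum does not.
"""

from pathlib import Path

from chlamyflux.scenarios import ScenarioConfig, run_scenario

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    # full bundle (incl. the ~1 MB mode set) goes to scratch/; the summary
    # table is the result of record
    res = run_scenario(ScenarioConfig(scenario="full", output_dir=ROOT / "scratch" / "full"))
    df = res.summary
    (ROOT / "results").mkdir(exist_ok=True)
    df.to_csv(ROOT / "results" / "yield_summary_full.tsv", sep="\t", index=False)
    print(df.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    print()
    for scheme in ("knockout", "weighted"):
        sel = df[(df.scheme == scheme) & df.mean_increases.notna()]
        up = sel[sel.target != "Arg"]
        print(f"{scheme}: mean yield increases for "
              f"{int(up.mean_increases.sum())}/{len(up)} amino acids; "
              f"maximum never increases: {bool(up.max_not_increased.all())}")
    arg = df[(df.target == "Arg") & (df.scheme == "knockout")].iloc[0]
    print(f"arginine under complete knockout: {int(arg.n_modes)} modes "
          "(argininosuccinate lyase is essential)")


if __name__ == "__main__":
    main()
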