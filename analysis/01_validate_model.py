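#!/usr/bin/env python
"""Validate the packaged core network of night-time nitrogen metabolism.

Checks referential integrity and per-reaction carbon balance, and reports
the model dimensions and the regulated-enzyme set.  Writes
results/model_summary.tsv.
"""

from pathlib import Path

from chlamyflux.network import load_core_model, validate_carbon_balance

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    net = load_core_model()
    violations = validate_carbon_balance(net)
    print(f"model: {net.name}")
    print(f"  reactions:   {len(net.reactions)}")
    print(f"  metabolites: {len(net.metabolites)} "
          f"({len(net.internal_metabolites)} internal)")
    print(f"  externals:   {sorted(net.config.external)}")
    print(f"  carbon sources: {sorted(net.config.carbon_sources)}")
    print(f"  targets:     {list(net.config.targets)}")
    print(f"  regulated:   {sorted(net.config.regulated_reactions)}")
    if violations:
        print("CARBON BALANCE VIOLATIONS:")
        for v in violations:
            print("  ", v)
    else:
        print("  carbon balance: clean (cofactor moieties excluded)")
    OUT.mkdir(exist_ok=True)
    with open(OUT / "model_summary.tsv", "w") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"reactions\t{len(net.reactions)}\n")
        fh.write(f"metabolites\t{len(net.metabolites)}\n")
        fh.write(f"internal_metabolites\t{len(net.internal_metabolites)}\n")
        fh.write(f"carbon_balance_violations\t{len(violations)}\n")
        fh.write(f"regulated_reactions\t{','.join(sorted(net.config.regulated_reactions))}\n")


if __name__ == "__main__":
    main()
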