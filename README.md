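# afcua

Cost-utility microsimulation of three anticoagulation strategies for newly
diagnosed atrial fibrillation: standard warfarin dosing (`sdw`),
pharmacogenetic-guided warfarin dosing (`gtw`), and dabigatran 150 mg twice
daily (`dab150`).

Each virtual patient is advanced in daily cycles over a five-year horizon.
Warfarin patients occupy an INR category (below / within / above the 2–3
therapeutic range) each day; daily probabilities of major bleeding and
thromboembolic events depend on that category through hazard-scale relative
risks. Events resolve into subtypes (intracranial vs gastrointestinal
bleeds; stroke, MI, PE, DVT), fatality, and mild/severe sequelae.
Intracranial bleeding stops anticoagulation permanently, gastrointestinal
bleeding for 30 days. Discounted (3%/yr) direct costs and
utility-weighted QALYs are accrued daily. The three arms are run on shared
virtual populations with common random numbers, so incremental results are
resolvable well above Monte-Carlo noise.

## Layout

| module | contents |
| --- | --- |
| `afcua.parameters` | every model input with baseline, sensitivity range and PSA distribution family; YAML (de)serialization; distribution fitting from 95% ranges; PSA draws |
| `afcua.cohort` | virtual population generation; counter-based random substreams (common random numbers across arms) |
| `afcua.engine` | daily-cycle simulator, event resolution, cost/QALY accrual, and a deterministic first-event expectation oracle |
| `afcua.cea` | raw cost/utility ratios, ICUR, strict/extended dominance frontier, net monetary benefit, acceptability curves |
| `afcua.sensitivity` | one-way scenario runner, probabilistic sensitivity analysis, TTR threshold search |
| `afcua.cli` | `afcua` command-line interface |

The baseline parameter file (`params_table1.yaml`) and one YAML fixture per
published one-way scenario ship under `afcua/data/`.

## CLI

```bash
# base-case run (defaults: 10,000 patients x 1,000 replicates; scale down for a desk run)
afcua run --n 2000 --reps 10 --seed 1 --out results/

# recompute dominance from an existing summary table
afcua frontier results/arm_summary.csv

# one-way scenarios (built-in published set, or --scenario file.yaml)
afcua oneway --n 2000 --seed 1 --out results/

# probabilistic sensitivity analysis + acceptability curve
afcua psa --n 500 --iters 100 --seed 1 --out results/

# TTR threshold at which genotype-guided dosing becomes cost-effective
afcua threshold --n 2000 --wtp 50000 --seed 1
```

Structural switches: `--literal-rr-labels` applies the relative risks to
the INR states exactly as printed in the source table (the default uses
the clinically coherent assignment: bleeding elevated above range,
thromboembolism below), `--literal-ich-utilities` keeps the printed
(inverted) intracranial-bleed utility ordering, and
`--additive-ttr-uplift` reads the genotype-guided TTR uplift as additive
percentage points rather than a relative multiplier.

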