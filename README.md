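# tavicea

A Markov cohort cost-effectiveness model of **transcatheter aortic valve
implantation (TAVI)** for severe aortic stenosis, from a national-payer
perspective, across three surgical-risk groups:

| Risk group   | Intervention | Comparator            |
|--------------|--------------|-----------------------|
| intermediate | TAVI         | surgical replacement (sAVR) |
| high         | TAVI         | surgical replacement (sAVR) |
| inoperable   | TAVI         | medical therapy       |

It is aimed at health-economics analysts who want a tested, scriptable
re-implementation of this decision model: a transparent engine, packaged
input tables, and one-way + probabilistic sensitivity analyses, instead of
a spreadsheet.

## The model

A cohort moves through nine health states — NYHA classes I–IV with and
without stroke history, plus death — on 1-month cycles over a 15-year
horizon. Each cycle applies, in order, arm-level death, major stroke
(flipping the stroke-history flag), and NYHA class movement. Other
clinical events (bleeding, pacemaker, hospitalizations, re-interventions,
…) are costed incidences rather than states.

Interval inputs (probability *p* over an *n*-month band) become monthly
probabilities `1 − (1 − p)^(1/n)`. Mortality beyond month 60 follows an
OLS line through the annualized probabilities of years 2–5; event rates
beyond month 24 carry the last band forward. With discount factor
`d(t) = 1.03^(−t/12)`:

- LY  `= Σ_t alive(t) · d(t) / 12`
- QALY `= Σ_t Σ_s occ(t, s) · u(s) · d(t) / 12`
- Cost `= index cost + Σ_t Σ_e events_e(t) · c_e · d(t)`
- ICER `= ΔCost/ΔLY`, ICUR `= ΔCost/ΔQALY`

The utility and NYHA-transition inputs are not publicly available; the
package ships clearly-labelled synthetic stand-ins (see
`docs/methods.md`), so QALY-based outputs demonstrate the machinery while
cost and life-year outputs are fully determined by the packaged tables.
Supply your own `utilities.csv` / `nyha_transitions.csv` to override.

## Worked example

```bash
tavicea base-case --fixture inoperable_base --outdir runs/inoperable
```

prints (abridged):

```json
{
  "risk_group": "inoperable",
  "intervention": {"arm": "tavi",    "discounted_cost": 36396, "discounted_ly": 3.23, "discounted_qaly": 2.63},
  "comparator":   {"arm": "medical", "discounted_cost": 19602, "discounted_ly": 1.60, "discounted_qaly": 0.96},
  "incremental":  {"delta_cost": 16794, "delta_ly": 1.633, "delta_qaly": 1.670,
                   "icer": 10286, "icur": 10054, "dominance": "none"}
}
```

Reading: over 15 discounted years an inoperable TAVI patient costs €36,396
and lives 3.23 years versus €19,602 and 1.60 years under medical therapy,
so TAVI buys each extra life year for ≈ €10,286 (the ICUR of €10,054/QALY
uses the synthetic utility tables and is illustrative). The output
directory receives `results.json`, per-arm cohort traces, a per-item cost
breakdown and a reproducibility manifest.

Other entry points, all sharing a YAML run configuration:

```bash
tavicea scenario    --fixture intermediate_micro   # micro-costing + rehabilitation
tavicea sensitivity --fixture high_base --seed 7   # tornado.csv, psa_draws.csv, ceac.csv
tavicea synth       --outdir synth/                # synthetic ground-truth CSVs
```

or from Python:

```python
from tavicea import load_parameter_set, run_comparison, owsa, psa, ceac

params = load_parameter_set("intermediate_base")
tavi, savr, ce = run_comparison(params)
tornado = owsa(params, perturbation=0.2, top_n=20)
curve = ceac(psa(params, n_draws=1000, seed=1))
```

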