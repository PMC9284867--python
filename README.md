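# pharmaproc

Analysis pipeline for public drug-procurement ledgers: from raw purchase
records to inflation-adjusted **weighted average price per mg (WAP/mg)**,
expenditure and volume shares, the lowest-price **avoidable expenditure**
counterfactual, and volume–price **pattern classification** — plus a
seeded synthetic ledger generator so the whole pipeline can be exercised
and validated offline.

The package is aimed at pharmacoeconomics and drug-utilization
researchers working with procurement registries such as Brazil's SIASG
(the federal purchasing system), where each row is one purchase event:
a medicine, a buyer, a month, a quantity of dispensing units and a
nominal unit price. The motivating application is federal procurement of
breast-cancer antineoplastics (anastrozole, docetaxel, exemestane,
letrozole, paclitaxel, tamoxifen, trastuzumab, vinorelbine) by four
purchaser categories — Ministry of Education (ME, university hospitals),
Ministry of Health (MH), Ministry of Defense (MD) and Other Institutions
(OI, mainly state/municipal health authorities) — over 2013–2019.

## Method

For purchases *i* in a stratum (medicine × year × purchaser category),
with quantities *qᵢ* (units), strength *s* (mg/unit) and deflated unit
prices *pᵢ*:

* volume standardised to mg: `V = Σ qᵢ·s` (several study drugs have no
  defined daily dose, so mg is the comparable unit);
* expenditure `E = Σ qᵢ·pᵢ`, with nominal prices restated to a reference
  month via a monthly consumer-price index: `p = p_nom · idx[ref]/idx[m]`;
* weighted average price per mg: `WAP/mg = E / V`;
* within each medicine × year, the category paying the lowest WAP/mg is
  the **benchmark** `w*`; every other category's counterfactual spend is
  `V·w*`, its **avoidable expenditure** `AE = E − V·w*  (≥ 0)`, and the
  **additional quantity** purchasable with that money is
  `AE / w*` mg, i.e. `AE / (w*·s)` dispensing units;
* each medicine × category annual trajectory is classified by the
  Spearman rank correlation ρ between annual volume and annual WAP/mg:
  *market* (ρ ≤ −0.5, price falls as volume rises), *inelastic*
  (|ρ| < 0.3), otherwise *indeterminate*; fewer than 4 usable years is
  *insufficient data*.

Only *active* purchases made through *competitive bidding* are analysed,
and a medicine is included only if the configured inclusion category
(default MH) bought it in at least *k* (default 5) distinct calendar
years of the window.

## Worked example

```python
from pharmaproc import (default_config, generate, filter_eligible,
                        select_medicines, adjust_records, aggregate,
                        avoidable_table, StudyConfig)

ds = generate(default_config(seed=7))          # synthetic 2013-2019 ledger
eligible = filter_eligible(ds.records)         # active + competitive only
print(len(ds.records), len(eligible))          # 3953 3360
print(len(select_medicines(eligible, StudyConfig())))   # 10

deflated = adjust_records(eligible, "2019-07", ds.index)
agg = aggregate(deflated, ds.master)           # medicine x year x category
av = avoidable_table(agg, ds.master)
ok = av[~av["avoidable_expenditure"].isna()]
print(round(ok["avoidable_expenditure"].sum()))         # 172346641
```

The generated scenario plants price multipliers ME 1.1, OI 1.25, MD 1.5
over the benchmark MH price, so nearly all avoidable spend falls outside
MH. One medicine × year block of `av` (the trastuzumab-like drug, 2015):

```
category  actual_wap benchmark_category  avoidable_expenditure  additional_units
      ME   39.764097                 MH              7750218.0               494
      MH   35.643833                 MH                    NaN                 0
      MD   53.314025                 MH              5908912.0               377
      OI   44.780372                 MH              6492425.0               414
```

MD paid 53.31 per mg against the MH benchmark of 35.64, so 5.9 million
in reference-month currency was avoidable — enough for 377 further
440-mg ampoules at the benchmark price. The benchmark category's own
cell is NA by construction.

The same pipeline runs from the shell:

```sh
pharmaproc simulate --seed 7 --out-dir data/
pharmaproc run --purchases data/purchases.csv --index data/index.csv \
               --master data/master.csv --out-dir out/
```

writing `table1_volume.csv`, `table2_spending.csv`,
`table3_avoidable.csv`, `patterns.csv`, `wap_volume_series.csv` and a
JSON run manifest with the filter-cascade counts and input digests.

## Reference tables

`pharmaproc.reference` ships, as plain CSVs, the published summary
tables of the 2013–2019 Brazilian federal procurement study of
breast-cancer antineoplastics (volumes in mg, spending in R$, avoidable
expenditure and additional units per category and year).
`reference.reconcile()` re-runs the pipeline's share and
additional-quantity formulas over the printed cells and returns the
headline figures; `pharmaproc fixtures --out-dir DIR` exports the CSVs.

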