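# Cohort table column dictionary

One row per patient (CSV). Outcome variables carry `_baseline` and `_year1`
suffixes for the two visits.

| column | type | meaning |
| --- | --- | --- |
| `patient_id` | str | unique identifier |
| `age_years` | float | age at baseline |
| `sex` | `female` / `male` | reference level: female |
| `map_mmHg` | float | mean arterial pressure |
| `smoking` | `never` / `ever` / `current` | reference level: never |
| `hypertension` | 0/1 | diagnosis (reference: 0) |
| `diabetes` | 0/1 | diagnosis (reference: 0) |
| `hypercholesterolemia` | 0/1 | diagnosis (reference: 0) |
| `resting_etco2_mmHg` | float | optional sensitivity covariate |
| `cvr_sgm`, `cvr_nawm`, `cvr_wmh` | float | baseline CVR per tissue, %/mm Hg |
| `wmh_pct_icv_*` | float | WMH volume, % of intracranial volume |
| `brain_pct_icv_*` | float | brain volume, % of intracranial volume |
| `pvs_bg_pct_roiv_*` | float | basal-ganglia PVS volume, % of region volume |
| `pvs_cso_pct_roiv_*` | float | centrum-semiovale PVS volume, % of region volume |
| `pvs_total_pct_roiv_*` | float | total PVS volume, % of region volume |
| `n_lacunes_*` | int | lacune count (visual rating; input, not computed) |
| `n_microbleeds_*` | int | microbleed count (visual rating; input) |
| `nihss_*` | int 0–42 | NIH Stroke Scale |
| `mrs_*` | int 0–6 | modified Rankin Scale |
| `moca_*` | int 0–30 | Montreal Cognitive Assessment |
| `recurrence` | 0/1 | recurrent stroke/TIA or new infarct over follow-up |

Missing values are allowed anywhere except `patient_id`; every model is fit
complete-case on the columns it uses.
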