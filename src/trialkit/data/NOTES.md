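# Packaged contingency tables

Both tables are day-28 outcome counts from the lopinavir-ritonavir trial
(Cao et al., NEJM 2020), 99 subjects on lopinavir-ritonavir and 100 on
standard care.

- `cao_mortality.csv` — deaths in the earlier stage of illness (<=12 days
  after symptom onset), deaths in the later stage (>12 days), and
  survivors. Collapsing the two death columns gives the 2x2 table
  ((19,80),(25,75)) with odds ratio 0.71 and Woolf 95% CI (0.36, 1.40).
- `cao_improvement.csv` — clinical improvement reached in days 1-7, 8-14,
  15-28, and no improvement by day 28.

Known discrepancy: collapsing `cao_improvement.csv` to improved vs not
gives ((78,22),(70,30)), whose odds ratio is (78*30)/(22*70) = 1.52 with an
uncorrected chi-square P of about .20. Secondary reanalyses of this trial
have quoted an odds ratio of 1.24 (95% CI 0.64-2.40, P=.53) for the same
collapse; those figures cannot be reproduced from the printed counts above
and their provenance is unclear, so this package reports only what the
counts imply.
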