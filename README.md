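# slklink

Tools for studying record linkage with the **SLK-581 statistical
linkage key** — the 14-character pseudo-identifier used across
Australian health and community-care datasets in place of full personal
identifiers — and for quantifying what using it costs compared with
full probabilistic linkage.

Many administrative collections (for example community-care minimum
datasets) carry only an SLK-581, while hospital and death-registration
datasets carry full identifiers and are already linked person-to-person
by a linkage unit's probabilistic **master linkage key (MLK)**.
Researchers who must link through the SLK-581 need to know how many
links they will miss, how many false links they will admit, and how
that biases downstream estimates such as hospitalisation rates before
death. This package provides the full apparatus to study that question
at desk scale: a calibrated synthetic data generator with hidden ground
truth, the five linkage strategies, and the evaluation statistics.

## The key and the strategies

The SLK-581 concatenates letters 2, 3, 5 of the surname, letters 2, 3
of the given name, date of birth as `DDMMYYYY`, and a sex code
(1/2/9), padded with dummy characters (`2` for short names, `9` for
missing names, `00000000` for a missing or invalid date of birth) so it
always has 14 characters. A key is *incomplete* when any component is
missing or invalid — including January-1 birth dates and ages over 110
years at the record's event date.

Five strategies link each death registration to hospital admissions:

| strategy | rule |
|---|---|
| `full_probabilistic` | follow the MLK person grouping (reference standard) |
| `basic_slk` | exact 14-character key equality only |
| `most_recent_slk` | match on each MLK person's key from their most recent separation (complete keys preferred), then take all their admissions |
| `most_frequent_slk` | as above with the person's modal complete key (ties to most recent) |
| `any_match_slk` | key-match first, then expand every hit to its full MLK person group |

Evaluation treats `full_probabilistic` as the standard: a person has a
*missed link* when the reference links them a record the strategy does
not, and a *false positive* when the strategy links a record the
reference does not; one person can have both.

## Worked example

The numbered scripts under `analysis/` run one desk-scale study
(6 000 persons, 60% decedents, nine financial years, seed 581):

```sh
python analysis/01_simulate.py   # generate data, audit SLK quality
python analysis/02_link.py       # run the five strategies
python analysis/03_evaluate.py   # compare, tabulate, write results/tables
```

`01_simulate.py` reports the key-quality audit — at the default
calibration 71.7% of private-hospital and 11.2% of public-hospital
admission records have an incomplete key (almost entirely missing
names), against 0.8% of death records — and verifies the injected MLK
error at 4.98/1000 missed and 3.06/1000 false-positive links.

`03_evaluate.py` then prints, for this run:

```
Person-level error rates vs the full-probabilistic reference:
  basic_slk          missed-link persons  88.5%   false-positive persons 0.39%
  most_recent_slk    missed-link persons   4.6%   false-positive persons 0.24%
  most_frequent_slk  missed-link persons   3.8%   false-positive persons 0.24%
  any_match_slk      missed-link persons   3.7%   false-positive persons 0.39%

Mean hospitalisations per decedent (full window):
  full_probabilistic  12.8 (12.4-13.2)
  basic_slk            8.5 (8.3-8.8)
  most_recent_slk     12.5 (12.1-12.9)
  most_frequent_slk   12.7 (12.3-13.1)
  any_match_slk       12.8 (12.3-13.2)
```

Reading: linking on the bare key misses at least one record for most
decedents — because a third of admission records carry no name and an
all-dummy key can never equal a named one — and understates mean
hospitalisations before death by a third (8.5 vs 12.8), while admitting
almost no false links (0.39% of persons). The combined strategies
recover nearly all of the shortfall. The per-year trend shows the
basic-key miss rate growing with distance from death (45.7% in the
death year rising to 59.2% eight years earlier in this run), and the
condition table shows the bias is condition-dependent: a
private-sector-affine condition (arthritis-like, rate ratio 0.48 under
`basic_slk` here) is under-ascertained far more than a public-affine
one (diabetes-like, 0.85), because private records carry the missing
names.

The same pipeline is scriptable on any directory of same-schema CSVs
through the CLI:

```sh
slklink all --seed 581 --n-persons 6000 --out-dir out
slklink simulate --config my_config.yaml --out-dir out
slklink link --out-dir out --strategies full_probabilistic,basic_slk
slklink evaluate --out-dir out
```

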