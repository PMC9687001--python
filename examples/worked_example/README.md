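# Worked example: a 12-gene, 2-stage miniature experiment

Every number in this fixture can be checked by hand.  The design:

* 12 genes, two stages (GV oocyte and 8-cell embryo);
* per stage: one replicate of each gradient fraction F1–F10 plus one
  transcriptome sample;
* **every sample column sums to exactly 10,000 counts** and **every
  transcript length is 1,000 nt**, so `TPM = 100 × count` with no further
  arithmetic;
* `g_b6` is the balancing gene that tops each fraction column up to
  10,000; its F3–F10 ranks are deliberately non-monotone (Spearman ρ = 0).

The fixture is generated by `polymodes.worked_example()` /
`polymodes.write_worked_example()`; these files are the committed copy.

## Hand-computed quantities (GV stage)

A = transcriptome TPM; P = mean TPM over F8–F10; M = mean over F3–F5;
TE = P/A.  The gradient statistic is Spearman's ρ between log2(TPM+1) and
fraction index over F3–F10 (8 points, one replicate), with the exact
permutation p-value: a perfectly monotone series has p = 2/8! ≈ 4.96e-5.

| gene  | A (TPM) | P (TPM) | M (TPM) | TE    | ρ (F3–F10) | mode |
|-------|---------|---------|---------|-------|------------|------|
| g_m1  | 2,000   | 10,000  | 2,000   | 5.0   | +1         | 1    |
| g_m2  | 300,000 | 90,000  | 40,000  | 0.3   | +1         | 2    |
| g_m3  | 250,000 | 45,000  | 45,000  | 0.18  | 0          | 3    |
| g_m4  | 30,000  | 8,000   | 70,000  | 0.267 | −1         | 4    |

Checks against the rules: g_m1 sits in the bottom abundance tertile with
the top-tertile TE and a significant rising gradient → mode 1.  g_m2 is
top-tertile abundant, rises significantly, TE below the top cut → mode 2.
g_m3 is abundant with bottom-tertile TE and no rising gradient → mode 3.
g_m4 has M = 70,000 ≥ 2 × P = 16,000 with a significant falling gradient →
mode 4.  All other genes classify as `none` at both stages (fraction
profiles flat; TE between the tertile cuts).

## Programs

`g_mat` is maternal-style: A = 80,000 TPM at GV vs 500 at 8C (160-fold);
`g_emb` mirrors it.  With only two stages the full program contrasts
(GV & MII vs pooled 8C/MOR/BL) cannot run here; the fixture documents the
abundance pattern only.

## CPE motifs

3'UTR sequences use a T-free background (`ACGGCAGCGA` repeats) so spliced
motifs are the only matches:

* `g_mat` contains `TTTTATTTTAT` → exactly **2** overlapping `TTTTAT`
  matches (positions 1 and 6 of the insert);
* `g_emb` contains no motif → 0;
* `g_m3` carries 5 motifs (2 overlapping + 3 spaced).

## UTR filter boundary

`g_mat` (5'UTR 90 nt) and `g_b1` (50 nt) are excluded from UTR feature
analyses; `g_b2` sits exactly at the 100 nt boundary and is excluded;
`g_b3` at 101 nt is retained.

Run it end to end:

```bash
python examples/00_worked_example.py
```
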