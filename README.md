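# mircascade

Discovery of **time-regulated gene–miRNA interaction candidates** from paired
differentiation time-course expression data.

Long-term stem-cell differentiation (e.g. hiPSC-derived cardiomyocytes
profiled over 30–120 days) changes the transcriptome only subtly at late
stages, which buries the few transcripts that actually track maturation.
`mircascade` implements a filter cascade that mines such data for miRNA→target
pairs whose expression moves in opposite directions over time — the classic
signature of post-transcriptional repression — together with a synthetic-data
generator with planted ground truth so every stage is testable without
downloading any accession.

The cascade, for a pair of log2 expression matrices (genes and miRNAs,
transcripts × samples, with per-sample day/replicate metadata):

1. **Detection** — keep transcripts whose day-mean log2 signal exceeds a
   detection floor at ≥ 6 distinct days.
2. **Segmental fold change** — split the course into phases (e.g. days 0–7,
   10–14, 20–120); a transcript is informative in a phase when its linear
   fold change FC = 2^(Δlog2) between the phase's first and last sampled day
   satisfies FC ≤ 0.8 or FC ≥ 1.2 (inclusive).
3. **Exponential trajectory** — keep transcripts whose day-mean curve fits a
   two-term exponential *y(t) = a·e^{bt} + c·e^{dt}* with goodness
   *R* ≥ 0.7, where *R* is the Pearson correlation between fitted and
   observed values.
4. **Interaction restriction** — intersect a validated miRNA→gene table
   (miRTarBase-style TSV with ordinal confidence classes) with the surviving
   transcripts, keeping high/very-high-confidence pairs.
5. **iFC ranking** — score each pair by the Pearson correlation *r* of its
   two day-mean trajectories (p from *t = r·√((n−2)/(1−r²))* on *n−2* df);
   *r* < 0 marks an inverse ("validated") pair, and the strict *r* < −0.5
   rule defines the high-stringency signature. Pairs are labelled
   **Profile 1** (gene up, miRNA down over time) or **Profile 2** (mirror).
6. **Cross-dataset concordance** — for each signature transcript, the
   percentage of external datasets whose day-0 → final-day fold-change
   direction agrees with the reference (pass at ≥ 50%).
7. **Random-forest stage evaluation** — transcript sets from successive
   stages compared by macro one-vs-rest ROC AUC of a day classifier under
   stratified cross-validation.

## Worked example

```python
import mircascade as mc

bundle = mc.generate(mc.canonical_config(seed=42))      # planted experiment
scheme = mc.SegmentScheme((("early", 0, 4), ("mid", 6, 8), ("late", 15, 30)))
result = mc.run_cascade(bundle.genes, bundle.mirnas, bundle.interactions,
                        mc.PipelineParams(segments=scheme))
for s in result.high_stringency[:3]:
    print(s.mirna_id, s.gene_id, round(s.pearson_r, 3), s.profile)
```

Running `python examples/03_rank_interactions.py` prints:

```
funnel: genes 510 -> 453 -> 104 -> 54; pairs 510 -> 12 -> 11 high-stringency
miRNA              gene             r        p  profile   planted
hsa-miR-p01        PGENE01     -0.998   0.0000  profile1  yes
...
hsa-miR-p06        PGENE06     -0.968   0.0003  profile1  yes
hsa-miR-bg0050     BGENE0394   -0.818   0.0247  profile1  no
```

Reading: of 510 input genes, 453 are detected, 104 are fold-change
informative in some phase, 54 have exponential trajectories; of the 510
interaction rows, 12 connect two surviving transcripts at high confidence
and 11 fall below *r* = −0.5. All 10 planted pairs are recovered at the top
of the ranking (r ≈ −1); one decoy edge slips in at r = −0.82.

The other scripts in `examples/` walk the fixture generator, the filter
funnel and the validation/evaluation stages one capability at a time.
A thin CLI mirrors the library (`mircascade run config.yaml`,
`mircascade simulate`, `mircascade filter`, ...).

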