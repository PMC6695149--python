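# zsens

**Which of my outcome measures is actually sensitive to the manipulation?**

Repeated-measures studies of stress, fatigue, training load or treatment
response routinely collect disparate metrics — reaction times in seconds,
mood-inventory scores in questionnaire points, salivary hormone
concentrations in µg/dL — and then struggle to say which of them responded
most strongly, because the measures live on incomparable scales. `zsens`
implements a z-score based procedure for making that comparison objective:

1. **Pool and standardize.** For each measure, pool all subjects and
   sessions and convert to standard scores, *z* = (*X* − *X̄*)/*σ*. Every
   measure now has grand mean 0 and SD 1.
2. **Quality-control gate.** Because z-scoring is a positive affine map,
   the one-way within-subject ANOVA across sessions must give *identical*
   F and p values on raw and standardized data. The pipeline verifies this
   per measure (to 1 × 10⁻⁹) before anything else is trusted.
3. **Omnibus ANOVA.** All measures are stacked into a single
   time × measure fully within-subject factorial ANOVA with
   Greenhouse–Geisser sphericity correction. The measure main effect is
   null by construction (every marginal z mean is 0); a significant
   time × measure interaction means the measures *differ* in how they
   track the manipulation.
4. **Per-measure follow-up.** One-way RM-ANOVA, orthogonal polynomial
   trend contrasts (linear/quadratic/cubic — the quadratic captures the
   inverted-U stress/recovery profile), and Fisher's-LSD-style paired
   comparisons for all session pairs, deliberately unadjusted for
   multiplicity.
5. **Sensitivity indices.** Per measure: significance counts (how many of
   the 3 trends, how many of the 6 session pairs at k = 4), and |Δz|, the
   absolute standardized change between baseline and each stress session.
   Measures are ranked by the lexicographic key
   (one-way significant, total significance count, max |Δz|).

Because studies of this kind rarely deposit raw per-subject data, the
package ships a first-class synthetic generator
(`zsens.synthetic`) that emulates the canonical design — 34 subjects ×
4 sessions × 18 measures (sustained-attention task, mood inventory,
spatial-memory task, four salivary hormones) with published baseline
means/SDs, a compound-symmetric random-intercept correlation structure,
and inverted-U effect trajectories injected in baseline-SD units.

## Worked example

```python
import zsens

data = zsens.generate_paperlike_study(seed=42)   # 34 x 4 x 18, balanced
bundle = zsens.run_pipeline(data)

for r in bundle.omnibus:
    print(f"{r.effect:15s} F({r.df_effect_gg:.1f},{r.df_error_gg:.1f})"
          f" = {r.F:8.3f}   p_GG = {r.p_gg:.4f}")
for measure, rank, key in bundle.ranking.entries[:5]:
    print(f"{rank:2d}. {measure:16s} key={key}")
```

prints

```
time            F(2.9,95.5) =   24.486   p_GG = 0.0000
measure         F(11.1,366.6) =    0.000   p_GG = 1.0000
time x measure  F(19.3,638.0) =    7.078   p_GG = 0.0000

 1. POMS_anger       key=(1, 5, 1.0320308052826102)
 2. POMS_depression  key=(1, 5, 0.9972042980390001)
 3. POMS_tmd         key=(1, 5, 0.9689389632800234)
 4. cortisol         key=(1, 5, 0.8857279546901733)
 5. POMS_vigor       key=(1, 5, 0.8503128893219281)
```

Reading the output: the session (time) main effect is large and
significant with Greenhouse–Geisser-corrected fractional df; the measure
main effect is exactly null (F ≈ 0, p = 1) because standardization forces
every measure's grand mean to 0 — this is the built-in correctness check;
and the significant time × measure interaction says the 18 measures
respond *differently* to the stressor. The ranking then orders measures
by their evidence of sensitivity: each key tuple is (one-way ANOVA
significant?, number of significant trend + pairwise tests, max |Δz|
between baseline and the stress sessions). Here the mood sub-scales and
cortisol top the list — they carry the largest injected effects in the
default generator — with |Δz| ≈ 0.85–1.03 pooled-SD units of change.

The same pipeline is available from the shell:

```bash
zsens simulate --seed 42 --out study.csv
zsens run --input study.csv --out reports/
zsens qc  --input study.csv          # QC gate only
```

`reports/` then contains `qc.csv`, `omnibus.csv`, `sensitivity.csv`
(one row per measure: one-way p, trend p's, all pairwise p's,
significance counts, |Δz|), `ranking.json` and `run_log.txt`.

Real data are read from the same long CSV layout
(`subject,session,measure,value`, one observation per row); subjects with
any missing cell are dropped (complete-case rule) before analysis.

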