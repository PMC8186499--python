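# hydroscreen

Screening anaerobic-digester microbiomes for hydrolytic candidate taxa.

In straw-fed biogas reactors, hydrolysis of cellulose and hemicellulose is
the rate-limiting step, but the organisms supplying the extracellular
cellulases and xylanases are usually unknown and individually rare.
`hydroscreen` implements a screening strategy that couples two weekly time
series measured on the same reactors — fluorometric hydrolase activities and
16S rRNA amplicon (ASV) community profiles — and ranks ASVs by how closely
their relative-abundance trajectories follow the enzyme activities. It is
aimed at microbiome researchers working on anaerobic digestion or similar
engineered ecosystems who want a reproducible, testable implementation of
this screening procedure, with a synthetic-data module that plants known
"responder" taxa so the whole pipeline can be validated without sequencing
data.

## The method

**Assay kinetics.** Slurry samples are incubated with
4-methylumbelliferyl(MUF)-linked substrate mimics (MUF-cellobioside,
MUF-xylopyranoside) at substrate-saturating (V_max) conditions, and MUF
fluorescence is read every 5 min for ≥ 2 h. The activity is the initial
linear (zero-order) slope: the longest window from the first reading with
linear-fit r² ≥ 0.98 is fitted by OLS, converted through a matrix-matched
MUF standard curve (AU → µmol L⁻¹), scaled to mg MUF L⁻¹ h⁻¹
(× 60 × 0.17617 mg µmol⁻¹), divided by the slurry dilution, corrected
against heat-inactivated blanks (floored at 0), and averaged over the two
substrate concentrations.

**Community profiling.** Samples with fewer than 10,000 reads are removed;
counts are closed to relative abundances; alpha diversity uses
bias-corrected Chao1, `S_obs + f₁(f₁−1)/(2(f₂+1))`, and Shannon
`H = −Σ pᵢ ln pᵢ` (nats).

**Screening.** For each reactor–enzyme pair, activity days are aligned with
the nearest sequencing day (≤ 3 days), both the activity series and each
ASV's relative-abundance trajectory are z-scored, `z = (x − x̄)/s`, and a
two-sample Kolmogorov–Smirnov test compares the two z-value distributions.
ASVs whose distribution is *not* distinguishable from the activity's
(p > α = 0.05) are retained; the p-value is exact (full enumeration over
label assignments) for m + n ≤ 16, where the usual asymptotics are poor.
Retained ASVs are ranked by the R² of the OLS regression of z-abundance on
z-activity, and the top 25 are reported with KS and regression statistics
and taxonomy — the candidate table.

**Support analyses.** Correspondence analysis (total inertia = χ²/N) for
unconstrained beta diversity; single-constraint redundancy analysis
(Hellinger-transformed by default) with R² = SS(fitted)/SS(total) and a
permutation test, `p = (1 + #{R²_perm ≥ R²_obs})/(1 + n_perm)`; Pearson
correlations over day windows for methane-production-rate comparisons.

**Synthetic data.** Activity profiles follow a lag–rise–decline shape;
communities have a log-normal rank-abundance background with Dirichlet
compositional noise and multinomial sampling at realistic depths
(~54,000 ± 21,000 reads); planted responders at 0.01–0.5 % relative
abundance follow `p(day) ∝ exp(k·w(day))` where `w` correlates with the
z-scored activity at a chosen tracking level, and their identities are
recorded for recovery scoring.

## Worked example

```python
from hydroscreen.simulate import simulate_reactor
from hydroscreen.screening import screen

series, table, taxonomy, truth = simulate_reactor("R2", seed=42)
ranking = screen("R2", "cellulase", table, taxonomy, series["cellulase"])
print(ranking.table.head(5).to_string(index=False))
```

prints

```
 rank  asv_id   taxonomy  ks_D     ks_p  r_squared    slope  mean_rel_abundance
    1 ASV1977 SimGenus37   0.4 0.400471   0.943634 0.971408            0.000087
    2 ASV1542  SimGenus9   0.4 0.400471   0.724426 0.851132            0.002984
    3 ASV1714 SimGenus29   0.4 0.400471   0.717237 0.846898            0.000582
    4 ASV1083 SimGenus38   0.2 0.988261   0.709880 0.842544            0.000290
    5 ASV1305 SimGenus24   0.2 0.988261   0.701773 0.837719            0.000267
```

Each row is a candidate ASV: `ks_D`/`ks_p` are the two-sample KS statistic
and exact p-value comparing its z-scored trajectory with the z-scored
cellulase activity (large p = similar distributions); `r_squared` and
`slope` come from the z-on-z regression (on z-scores the slope equals the
Pearson correlation and R² its square); `mean_rel_abundance` shows these
candidates are rare (0.01–0.3 % here). Nine of the ten planted responders
appear in this top-25.

The same run from the shell:

```
hydroscreen run-all --seed 42 --outdir out/
```

writes activity, diversity and ordination summaries plus six candidate
tables (3 reactors × 2 enzymes) and a manifest; re-running with the same
seed reproduces every table byte for byte.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full synthetic pipeline end to end and the planted-responder
recovery benchmark (500 background ASVs, 10 responders, ~50k reads per
sample, 11 weekly samples) at two tracking levels, printing the per-level
median recovery, and writes the results JSON.
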