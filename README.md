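# somarsa

Multivariate pattern analysis of the somatosensory homunculus: does a patch
of primary somatosensory cortex (S1) carry information only about "its" body
part, or is task-relevant information distributed along the whole
medio-lateral strip?

Classical fMRI mapping answers with *selectivity*: mean activation (z versus
rest) peaks in the body part's primary zone and vanishes elsewhere.
`somarsa` implements the complementary *information-content* analysis: it
estimates condition response patterns with a block-design GLM, and measures,
in selectivity-defined regions of interest (ROIs) and in equal-height bands
along the strip, the cross-validated squared Mahalanobis distance
(**crossnobis**) between condition patterns,

```
d_ij = 1 / (M (M-1) P) * Σ_{m ≠ n} (b_i,m − b_j,m) · Σ̂_λ^{-1/2} Σ̂_λ^{-1/2} (b_i,n − b_j,n)
```

where `b_c,m` is condition *c*'s pattern estimated from run *m*, `P` the
voxel count, and `Σ̂_λ` the voxel noise covariance estimated from GLM
residuals with shrinkage toward its diagonal (multivariate noise
normalization: noisy voxels are down-weighted). Cross-validating the inner
product over independent runs makes the estimator unbiased — its
expectation is zero (negative values allowed) when two patterns differ only
by noise — so a group-level distance above zero is evidence of information
content, whether or not the region is *activated*.

Because no real scans are needed to study the method, the
package ships a ground-truth simulator: a 1-D cortical sheet with Gaussian
somatotopic activation zones, weak mean-free distributed condition patterns
across the whole sheet, a topographic similarity gradient between adjacent
subparts, and spatially/temporally correlated heteroscedastic scanner noise.
Every analysis can therefore be validated against known ground truth, and
the full experimental logic (three tasks — body, face, fingers; winner-takes-all
ROI definition from an independent localizer; band-wise strip profiles;
Bonferroni-corrected group inference with a Shapiro–Wilk/Wilcoxon gate and
Greenhouse–Geisser-corrected repeated-measures ANOVA) runs end-to-end on
synthetic cohorts.

Intended users: neuroimaging researchers who want a transparent, tested
reference implementation of crossnobis RSA for block designs, and
methodologists studying when "information without activation" is and is not
recoverable.

## Worked example

Simulate a default 8-subject body-task cohort (3 body parts × 2 actions, 8 s
blocks, 4 runs, TR 1.45 s), define the leg/hand/face ROIs from a simulated
localizer (50 most selective voxels each), and test the body-part
dissimilarities:

```bash
somarsa run --task body --subjects 8 --seed 7 --out results/body_demo
```

prints

```
nonprimary_dissimilarities_positive: PASS
nonprimary_univariate_not_significant: PASS
primary_only_univariate_selectivity: PASS
primary_univariate_significant: PASS
wrote results to results/body_demo
```

and `results/body_demo/dissimilarity_tests.csv` holds the one-tailed
one-sample tests (α = 0.017, Bonferroni for three body-part pairs per ROI):

```
region              comparison  statistic     p     d  significant
   leg dissimilarity:feet-hand     11.457 0.000 4.051         True
   leg dissimilarity:feet-lips     14.728 0.000 5.207         True
   leg dissimilarity:hand-lips      4.276 0.002 1.512         True
  hand dissimilarity:feet-hand     14.883 0.000 5.262         True
  hand dissimilarity:feet-lips      8.848 0.000 3.128         True
  hand dissimilarity:hand-lips      9.223 0.000 3.261         True
  face dissimilarity:feet-hand     11.306 0.000 3.997         True
  face dissimilarity:feet-lips     13.411 0.000 4.741         True
  face dissimilarity:hand-lips     12.039 0.000 4.256         True
```

Read the third line: in the *leg* ROI — defined purely by foot selectivity —
the hand–lips pattern distance is significantly above zero (t(7) = 4.28,
Cohen's d = 1.51) even though neither hand nor lips activates that region
(`univariate_tests.csv` shows their mean z levels are not significant
there). That is the headline phenomenon: information content about remote
body parts is present across the homunculus. The same directory contains the
per-subject RDMs (`rdms.csv` / `rdms.json`), MDS embeddings
(`mds_coordinates.csv`), band profiles, a JSON summary of the qualitative
checks and a manifest with config hash and output checksums; re-running the
same config reproduces byte-identical tables.

The same entry points exist as a library (`somarsa.run_experiment`,
`somarsa.simulate_cohort`, `somarsa.crossnobis_rdm`, ...), and the stage
commands `somarsa simulate|glm|rois|rsa|bands|stats|report` operate on
directories of NIfTI volumes and TSV event files, so user-supplied beta
images (`somarsa.io.patterns_from_nifti`) can enter at the RSA stage.

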