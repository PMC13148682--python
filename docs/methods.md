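# Methods

## The analysis

`netretest` quantifies the test–retest reliability of graph metrics computed
on brain-network functional connectivity. The unit of analysis is one
functional scan: the node-by-time matrix of mean BOLD signals extracted
from one predefined network (9–23 nodes) for one subject, session and scan
condition (resting state or one of three movie-watching conditions). The
pipeline is:

1. **Preprocessing** — each node's series is replaced by its OLS residual
   against an intercept plus nuisance regressors (the standard set is six
   rigid-body motion parameters, their first temporal derivatives, and
   CSF/white-matter/whole-brain global signals — 15 columns), then band-pass
   filtered to 0.01–0.1 Hz with an order-4 Butterworth applied
   forward–backward (zero phase). Regression runs before filtering; the
   order is fixed. Derivatives are backward differences with the first
   sample zero-padded.
2. **Connectivity** — the node-by-node Pearson correlation matrix
   (sample covariance available as a config switch; correlation is the
   default because the fixed edge threshold of 0.1 is only meaningful on a
   correlation scale).
3. **Thresholding** — edge (i, j) is kept with its signed value iff
   |r_ij| > τ (default τ = 0.1, strict inequality); the rule applies
   symmetrically to positive and negative edges and the diagonal is removed.
4. **Graph metrics** — five per scan, on the signed weighted thresholded
   graph: weighted degree centrality (signed sum of incident weights; a
   magnitude option exists), binary clustering coefficient, betweenness
   centrality, global efficiency and mean shortest path length. Shortest
   paths are **hop counts** on the binary support ("smallest number of
   links"), never weight-derived, so negative weights never enter a
   distance. Betweenness is normalised by (n−1)(n−2)/2 unordered pairs.
   Disconnected pairs contribute 0 to efficiency and are excluded (and
   counted) from mean path length — the only pair of conventions that keeps
   both metrics finite on graphs thresholding actually produces. Nodes with
   fewer than two neighbours get clustering 0. The scan-wise summary is the
   node average of each nodal metric.
5. **Reliability** — for each (network × condition × metric) cell, the
   subjects-by-sessions matrix of scan-wise values enters a two-way
   mixed-effects ANOVA (subjects random, sessions fixed) and the
   consistency ICC is

       ICC(3,1) = (MSp − MSe) / (MSp + (d − 1)·MSe)

   with d the number of sessions. Negative raw ICCs are clamped to 0 (both
   values reported). Categories use half-open bands: poor [0, 0.2), fair
   [0.2, 0.4), moderate [0.4, 0.6), good [0.6, 0.8), excellent [0.8, 1].
   The absolute-agreement ICC(2,1) is deliberately not implemented.
   Subjects with missing cells are dropped listwise (logged).
6. **Permutation inference** — conditions are compared by permutation:
   under the null, each subject's full session row is exchangeable between
   the two condition labels, so a null draw swaps rows per subject with
   probability 1/2 (both sessions move together, preserving the
   within-subject pairing the ICC depends on) and recomputes the clamped-ICC
   difference. Two-sided p = (1 + #{|null| ≥ |obs|}) / (B + 1) with
   B = 5000 by default. q-values are Benjamini–Hochberg step-up over the
   whole (network × metric × movie-vs-rest) family.

## The synthetic cohort generator

No public data exist for the emulated study design, so the generator is the
package's testbed. It reproduces the acquisition geometry — 33 subjects,
2 sessions, 4 conditions, 14 networks of 9–23 nodes, TR = 0.719 s, 834
timepoints per 10-minute scan — under a variance-components model: per
upper-triangle edge,

    w[s, t] = base + b[s] + e[s, t],  b ~ N(0, σ_b²),  e ~ N(0, σ_w²),

mirrored for symmetry, diagonal pinned at 1. The theoretical edge ICC is
σ_b²/(σ_b² + σ_w²), known exactly, which is what downstream estimation must
recover. Each session's latent matrix is projected to the nearest
positive-definite correlation matrix (eigenvalue clipping at a floor of
1e-8, re-standardised to unit diagonal; the clip floor is set 10× above the
acceptance tolerance because plain clip-at-floor can oscillate just below it
after re-standardisation; the projected matrix is the documented ground
truth for empirical covariance checks). Scans are i.i.d. multivariate
Gaussian draws via Cholesky, plus optional white observation noise.

Defaults: σ_b = 0.18, σ_w = 0.09 (theoretical edge ICC 0.8, the level a
well-measured network study aspires to), base connectivity 0.2 (a typical
mean within-network correlation), observation noise 0. The total edge
spread (sd ≈ 0.2) is kept small enough that PD repair is mild and the
finite-sample correlation noise at 834 timepoints (sd ≈ 0.03 per edge)
attenuates the edge ICC by well under the testing tolerance.

Reproducibility: one global seed; every scan, subject deviation and session
deviation uses its own RNG substream derived by SHA-256 hashing of the
(seed, labels) tuple, so generation order never changes results and
identical configs are bit-identical.

**What the generator does not emulate** — haemodynamics, temporal
autocorrelation, head motion, physiological confounds, non-Gaussian tails,
or any real spatial structure in the networks. Passing tests therefore
demonstrate the *statistical machinery* (estimation, thresholding
arithmetic, ANOVA, permutation calibration), not robustness to real fMRI
artefacts.

### Preprocessing of synthetic data

Because generated series are spectrally white, the 0.01–0.1 Hz band holds
only ≈13% of their power: band-pass filtering them discards roughly 87% of
the effective degrees of freedom, inflating edge-correlation sampling error
(sd ≈ 0.03 → ≈ 0.09) with noise that is condition-independent, and it also
correlates the sampling errors of different edges so node-averaged metrics
no longer average it away. On white data filtering is pure information
loss — its purpose (removing drift and physiological bands) addresses
artefacts the generator does not produce. The pipeline therefore keeps the
preprocess stage on by default for manifest (real) data, while the
reliability-contrast analyses of synthetic cohorts (planted-effect checks,
edge-ICC recovery) run with `preprocess=False`.

## Parameter choices that matter

| parameter | default | units | why |
|---|---|---|---|
| `threshold_tau` | 0.1 | correlation | fixed-value edge retention rule |
| `sigma_between` | 0.18 | correlation sd | edge ICC 0.8 with mild PD repair |
| `sigma_within` | 0.09 | correlation sd | as above |
| `base_connectivity` | 0.2 | correlation | typical within-network mean FC |
| `n_timepoints` | 834 | samples | 10 min at TR 0.719 s |
| `n_permutations` | 5000 | draws | p-resolution 1/5001 |
| bandpass | 0.01–0.1 | Hz | standard resting-state band |

## Numerical and design choices

- **Covariance vs correlation**: the connectivity kind is a config switch
  with correlation the default; a 0.1 threshold on covariances would depend
  on signal scale.
- **Strict threshold inequality** (|w| > τ): ties at exactly τ are removed;
  the choice is arbitrary and recorded here.
- **Signed degree** is the default (retained edges keep their signed
  coefficient); magnitude degree is available via `absolute_degree`.
- **ICC denominators**: sums of squares computed directly (no iterative
  fit); cells with zero total variance return raw ICC 0 with a warning
  rather than NaN. Tiny negative residual sums from cancellation are
  floored at 0.
- **Half-open category bands** close the printed gaps between, e.g., 0.79
  and 0.8.
- **Permutation scheme**: the subject-row swap is this package's
  construction; the randomisation count (5000) is conventional. +1
  smoothing keeps p in (0, 1].
- **Listwise deletion** of subjects with missing cells before the ANOVA is
  this package's documented choice.
- **eMDN / extDMN** are treated as aliases of one network.
- **Problem sizes in the test suite**: the graph-metric oracle sweep is
  exhaustive over all weight-grid graphs up to 4 nodes plus ~1000 seeded
  5–6-node samples (exhaustive enumeration at 5+ nodes exceeds 10⁶–10⁹
  graphs); ICC recovery uses 50 replicate cohorts per level on one 10-node
  network; permutation calibration uses 500 null repetitions of 999
  permutations; planted-effect detection uses 20 full-geometry cohorts with
  the planted condition's σ_w quartered.

## Known limitations

- Reliability of the *node-averaged* metric on thresholded graphs is much
  lower than the edge-level ICC when the mean connectivity sits near the
  threshold: edges flipping in and out of the support add session-specific
  variance the averaging cannot remove. This is a property of fixed-value
  thresholding, visible in the default cohort's modest metric-level ICCs.
- No ICC confidence intervals, no nodal ICC maps, no weighted clustering or
  weighted path lengths, no proportional/density thresholding, no Fisher
  z-transform, no volumetric/NIfTI handling.
- The generator's i.i.d.-per-edge deviations ignore any covariance between
  edges sharing a node; real connectomes violate this.
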