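# eptx

Stochastic gene expression under long-range enhancer–promoter (E-P)
chromatin dynamics: polymer distance laws, distance-modulated telegraph
transcription, analytic stationary mRNA distributions, multimodality
analysis, and cross-entropy inference from single-cell mRNA-count
histograms.

## The problem

Enhancers activate promoters across tens to hundreds of kilobases, and how
often the two elements meet in 3D space shapes how strongly — and how
noisily — a gene is expressed. `eptx` implements a two-layer stochastic
model for this coupling and the statistical machinery to fit it to
smRNA-FISH-style count histograms measured across cell lines that differ
only in E-P genomic distance.

**Chromatin layer.** The locus is a bead-spring (Rouse) chain of N
monomers (one monomer ≈ 5 kb) with nearest-neighbour stiffness k_NN, plus
a harmonic E-P spring of stiffness k_EP between the enhancer monomer E and
promoter monomer P. Monomers follow overdamped Langevin dynamics
dr = −∇U/γ dt + √(2D) dB. The E-P spatial distance d_S = ‖r_E − r_P‖ then
has the exact stationary Maxwell–Boltzmann law

    p(d_S) = √(2/π) Θ⁻³ d_S² exp(−d_S²/2Θ²),   Θ² = Dγ / (k_NN/d_G + k_EP),

with d_G = |E − P| the genomic distance in monomers: d_G chain springs in
series, in parallel with the direct E-P spring.

**Transcription layer.** The gene is a telegraph (two-state) model — OFF→ON
at rate α, ON→OFF at rate β, transcription at rate μ while ON, degradation
at rate δ — whose activation and initiation rates respond to the current
distance through decreasing Hill curves α(d_S), μ(d_S) between contact
(α_max, μ_max) and detached (α_min, μ_min) values. For frozen chromatin
the stationary mRNA law is Poisson-Beta:
P(x) = ∫₀¹ Poisson(x; μ̃t) Beta(t; α̃, β̃) dt with rates in units of δ.

**Timescale separation.** When chromatin moves much faster than the gene
switches, the stationary law is Poisson-Beta at the distance-*averaged*
rates (`p_fast`); much slower, it is the Maxwell–Boltzmann *mixture* of
conditional Poisson-Beta laws (`p_slow`); in between, the convex
combination P ≈ P_fast/(1+ω) + ω P_slow/(1+ω), with
ω = min(α_min, μ_min) / V_max and V_max = (k_NN/d_G + k_EP)·d_99/(bγ)
the maximal chromatin velocity at the 0.99 distance quantile
(`p_stationary`). A hybrid Euler–Maruyama + thinned-jump simulator
(`simulate_coupled`) provides the trajectory-level ground truth.

**Inference.** Given per-line histograms Q_k and genomic distances, the
package minimizes the total cross entropy
H(Γ) = −Σ_k Σ_i Q_k(x_i) log P_k(x_i; Γ) over
Γ = (k_NN, k_EP, γ, α_min, α_max, β, μ_min, μ_max) by bounded multi-start
quasi-Newton optimization (equivalent to maximum likelihood), and ranks
model variants in which only α, only μ, or both respond to distance.

## Worked example

Fitting a synthetic six-line panel (promoter-only control plus enhancers at
112.2, 39.5, 23.1, 17.0 and 6.1 kb; 2000 cells per line):

```bash
python examples/05_fit_panel.py
```

```
panel:
  C1: distance       nan kb -> d_G=None monomers, observed mean 0.73 mRNA
  C2: distance  112.1710 kb -> d_G=  22 monomers, observed mean 2.17 mRNA
  ...
  C6: distance    6.0600 kb -> d_G=   1 monomers, observed mean 8.87 mRNA

total cross entropy: fitted 12.8141 (generating parameters give 12.8145)
  Theta(d_G= 1): generating 2.394  fitted 2.295
  Theta(d_G=22): generating 6.151  fitted 6.093
per-line KS distances: {'C1': 0.006, ..., 'C6': 0.0123}
```

Mean expression falls monotonically with genomic distance (8.9 → 0.7 mRNA);
the fit reaches the cross-entropy floor set by the generating parameters
and recovers the distance-law scale Θ(d_G) within a few percent, while the
per-line Kolmogorov–Smirnov distances (≤ 0.02) show the fitted
distributions overlay the histograms.

The other examples each demonstrate one capability: `01_distance_law.py`
(simulated chain vs the Maxwell–Boltzmann law), `02_timescale_limits.py`
(fast/slow/intermediate regimes vs the analytic limits),
`03_expression_trends.py` (mean/CV trends and power-law decay),
`04_modality_phases.py` (the five-phase modality sequence
U(OP) → B(OP+NOP) → T → B(2NOP) → U(NOP) along a k_EP sweep).

A thin CLI mirrors the library: `eptx panel | distribution | simulate |
phase | scan | fit | ks` (see `eptx --help`).

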