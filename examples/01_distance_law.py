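"""Stationary enhancer-promoter distance law of the chromatin chain.

Builds a 23-monomer bead-spring chain whose enhancer and promoter sit four
monomers apart with an extra E-P spring, simulates its Langevin dynamics,
and compares the sampled spatial distance d_S with the exact
Maxwell-Boltzmann law of scale Theta = sqrt(D*gamma / (k_NN/d_G + k_EP)).
"""

from scipy import stats

from eptx import PolymerSpec, ep_equilibrium, simulate_chain

spec = PolymerSpec(N=23, k_NN=1.0, k_EP=0.75, E=10, P=14, D=1.0, gamma=1.0)
law = ep_equilibrium(spec)
print(f"chain: N={spec.N}, d_G={spec.d_G} monomers, k_eff={spec.k_eff:.3f}")
print(f"analytic scale Theta = {law.theta:.4f} "
      f"(mean distance {law.mean:.4f}, 99% quantile {law.quantile(0.99):.4f})")

traj = simulate_chain(spec, seed=0, n_samples=100, n_replicates=100,
                      sample_stride=200)
d = traj.d_s_flat
ks = stats.kstest(d, law.cdf).statistic
var = traj.separations.reshape(-1, 3).var(axis=0)
print(f"simulated mean distance  {d.mean():.4f}  (theory {law.mean:.4f})")
print(f"per-axis separation variance {var.round(4)}  (theory {law.theta**2:.4f})")
print(f"KS distance simulation vs law: {ks:.4f}")
print("-> the simulated distance ensemble is statistically indistinguishable "
      "from the Maxwell-Boltzmann law; Theta summarizes the whole chain.")
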