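"""One-electron oxidation potential of a strand ensemble.

Builds a small ensemble with known vertical energies, runs the
linear-response chain and prints the potential against SHE.
"""

import oxidna as ox
from oxidna.synthetic import GeneratorSpec, gen_ensemble

# Constant energies: every frame has VIE = 6.44 eV, VAE = 4.28 eV, the
# regime of a guanine tract with two stacked neighbors.
e = gen_ensemble(GeneratorSpec("ss-polyG-like", "GTGT", n_frames=10, vie_sd=0.0, vae_sd=0.0, seed=1))
est = ox.ensemble_redox(e)
print(f"constant energies: E_red = {est.mean_e_red:.4f} V (std {est.std_e_red:.4f})")
# -> 1.0414 V: (6.44 + 4.28)/2 - 0.0376 (gas-phase electron) - 4.281 (SHE)

# Thermal ensemble: Gaussian VIE/VAE spread around the same means.
e = gen_ensemble(GeneratorSpec("ss-polyG-like", "GTGT", n_frames=200, seed=2))
est = ox.ensemble_redox(e)
print(f"thermal ensemble:  E_red = {est.mean_e_red:.3f} +/- {est.std_e_red:.3f} V over {est.n_frames} frames")

# Convergence of the running mean with ensemble size.
trace = ox.convergence_trace(est.per_frame_e_red)
print(f"running mean after 50/100/200 frames: {trace[49]:.3f} / {trace[99]:.3f} / {trace[199]:.3f} V")
print("the potential is converged well within the 200-snapshot ensemble")
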