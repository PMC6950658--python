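"""Covariate effect factors and prior-sensitivity analysis.

The multiplicative effect of a covariate change dX is exp(beta * dX).  With
the published posterior means of the motivating analysis, a 5-point rise in
excess body fat corresponds to a 21% risk increase and a 3-unit rise in the
injury rate to a 28% increase.  The second half refits a synthetic panel
under an alternate variance hyperprior and shows the risk surface barely
moves.
"""

import stcar
from stcar import MCMCConfig, PriorSpec, SimulationParams

for label, beta, dx in (("EBF +5 points", 0.038, 5.0), ("THI +3 units", 0.081, 3.0)):
    factor, pct = stcar.covariate_effect(beta, dx)
    print(f"{label:<15} beta={beta:.3f}: RR factor {factor:.3f}  -> +{pct}% risk")

graph = stcar.make_lattice_graph(3, 4)
panel, _ = stcar.simulate_panel(graph, 4, SimulationParams(seed=9))
sens = stcar.prior_sensitivity(
    panel, graph,
    base=PriorSpec(),                                        # Gamma(0.5, 0.0005)
    alternates=[PriorSpec(hyper_shape=0.001, hyper_rate=0.001)],
    config=MCMCConfig(n_chains=3, n_iterations=8_000, n_burnin=2_000, thin=10, seed=9))
print("\nprior sensitivity:")
print(sens[["spec", "hyper_shape", "hyper_rate", "dic", "max_abs_rr_diff"]]
      .to_string(index=False))
# max_abs_rr_diff is the largest change in any area-year posterior-mean RR
# relative to the base prior: small values mean the inference is robust to
# the hyperprior choice.
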