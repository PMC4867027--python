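"""Quantify estimator uncertainty by parametric bootstrap.

Simulates synthetic experiments from a fitted connection, re-estimates the
parameters on each replicate, and summarizes the distribution of relative
errors (bias, SD) and the correlations between parameter estimates.
Run with more replicates (several hundred) for publication-grade
numbers; 25 replicates already show the structure.
"""

from quantalem import StimulationProtocol, SynapticParameters, parametric_bootstrap

connection = SynapticParameters(N=17, q=0.18, sigma_q=0.06, U=0.27,
                                tau_D=202.0, tau_F=449.0, sigma_n=0.03)
protocol = StimulationProtocol("regular", 50.0, 8)

bs = parametric_bootstrap(connection, protocol, n_trials=28, n_reps=25, seed=99)

print(f"{'parameter':>10} {'bias':>8} {'rel SD':>8}")
for name in bs.param_names:
    print(f"{name:>10} {bs.bias[name]:8.3f} {bs.sd[name]:8.3f}")

i = {p: k for k, p in enumerate(bs.param_names)}
print(f"\ncorr(N, q)     = {bs.correlations[i['N'], i['q']]:+.2f}")
print(f"corr(N, U)     = {bs.correlations[i['N'], i['U']]:+.2f}")
print(f"corr(N, tau_D) = {bs.correlations[i['N'], i['tau_D']]:+.2f}")
print("\nBiases near zero and relative SDs below ~0.3 indicate accurate,")
print("nearly unbiased estimates at 28 trials.  Negative N-q correlation is")
print("the compensatory trade-off: overestimating the number of sites must")
print("be offset by a smaller quantal size to keep the response range.")
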