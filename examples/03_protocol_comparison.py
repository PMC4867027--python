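"""Compare stimulation protocols by Fisher information before recording.

For a population-average connection, computes the Fisher Information
Matrix of three protocols at matched stimulation frequency (5 Hz) and
recording time (118 s), and prints the resulting Cramér-Rao lower bounds
on the relative estimation error of each continuous parameter.
"""

from quantalem import StimulationProtocol, SynapticParameters, compare_protocols

connection = SynapticParameters(N=8, q=0.15, sigma_q=0.05, U=0.33,
                                tau_D=335.0, tau_F=321.0, sigma_n=0.03)
T, duration = 200.0, 118000.0
protocols = {
    "regular": StimulationProtocol("regular", T, 8, duration=duration),
    "poisson": StimulationProtocol("poisson", T, 8, duration=duration),
    "single_sweep": StimulationProtocol("single_sweep", T, 8, duration=duration),
}

bounds = compare_protocols(connection, protocols, n_mc=300, seed=11)

params = ("q", "sigma_q", "U", "tau_D", "tau_F")
print(f"{'protocol':>14} " + " ".join(f"{p:>8}" for p in params))
for name, eps in bounds.items():
    print(f"{name:>14} " + " ".join(f"{eps[p]:8.3f}" for p in params))
print("\nEntries are lower bounds on the achievable relative error; smaller")
print("is better.  Irregular stimulation probes the synaptic dynamics on")
print("many timescales at once, so the Poisson and single-sweep protocols")
print("dominate the regular one, most visibly for tau_F.")
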