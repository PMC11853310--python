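"""Per-site m6A calling from per-read modification probabilities.

Simulates 1,000 full-length reads over 10 adenosine sites modified at 30%
stoichiometry, calls sites with the default gates (modProb >= 0.5 per read,
coverage >= 25, frequency >= 5%) and writes the passed sites as bedMethyl.
"""

import permod

cfg = permod.GeneratorConfig(seed=3, n_reads=1000, n_sites=10,
                             stoichiometry=0.3, residual=0.0)
calls, truth = permod.simulate_modprob_dataset(cfg)

sites = permod.call_sites(calls, tau=0.5, min_cov=25, min_freq=0.05)
print(sites[["chrom", "pos", "coverage", "n_modified", "frequency",
             "passed"]].to_string(index=False))
# frequency estimates the 30% stoichiometry minus the reads whose modProb
# falls below the per-read threshold

permod.write_bedmethyl(sites[sites["passed"]], "sites.bed")
print(f"\n{int(sites['passed'].sum())} passed sites written to sites.bed")
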