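"""Run the micro -> macro consistency battery at reduced sample sizes.

Checks, by simulation, that the microscale process obeys its defining laws
and that its ensemble density reproduces the macroscopic equation in the
parabolic regime.  (The shipped full-size battery uses 10^4-10^5 samples;
this example trades power for speed.)
"""

from gliomodel.consistency import run_validation_suite

report = run_validation_suite(seed=0, n_paths=4000, n_kernel=20_000, n_density=8000)
print(report.summary())
print()
print("statistics: KS/chi-squared p-values (pass >= 0.01), MSD slope relative")
print("error (pass <= 5%), and L1 density distances (pass <= 0.1).")
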