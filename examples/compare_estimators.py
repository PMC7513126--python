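"""Benchmark all six estimators on the uniform truth at a small sample size.

Draws 300 samples of size 20 from the 9-bin uniform distribution, applies each
estimator, and reports the mean KL divergence from the truth in bits.  Plain
bin counting is included for reference: with 9 bins and n=20 it almost always
leaves empty bins, so its mean divergence is infinite.
"""

from nzest import BenchmarkConfig, EstimatorSpec, run_benchmark, summarize

config = BenchmarkConfig(
    distributions=("uniform",),
    estimators=tuple(
        EstimatorSpec(m) for m in ("bincount", "addone", "bayes", "addp", "kds", "nonzero")
    ),
    n_grid=(20,),
    reps=300,
    seed=42,
)
table = summarize(run_benchmark(config))
print(table[["estimator", "n", "mean_kl", "finite_mean_kl", "inf_fraction"]].to_string(index=False))
print(
    "\nThe maximum-entropy estimators (addone, bayes, nonzero) sit well below"
    "\naddp and kds: with few data they fall back toward the uniform"
    "\ndistribution, which here happens to be the truth.  bincount's mean is"
    "\ninfinite because any empty bin makes its divergence infinite;"
    "\ninf_fraction says how often that happened."
)
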