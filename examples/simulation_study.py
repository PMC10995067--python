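"""Run a small factorial Monte Carlo experiment and tabulate performance.

One cell: the linear-interaction mechanism at the base-case design, comparing
fixed-effect meta-analysis against degree-1 meta-regression over 100
replicates.  For each estimator and estimand the harness reports the mean
estimate, bias, 95% CI coverage, empirical SE and mean reported SE, each with
its Monte Carlo standard error.  (The full grid of the method-evaluation
study — scenarios x overlap levels x study counts x sample sizes — is the
same call with more factor levels; cells scale linearly and can be resumed
via ``run_grid(..., out_dir=...)``.)
"""

from agemeta.evalperf import CellConfig, run_cell, summarise, true_effects

cell = CellConfig(scenario_id=2, estimators=("fe", "mr1"))
replicates = run_cell(cell, replications=100, seed=11)
perf = summarise(replicates, true_effects(cell.scenario(), cell.centre))

cols = ["estimator", "estimand", "truth", "mean", "bias", "coverage",
        "empse", "meanse"]
print(perf[cols].round(4).to_string(index=False))
print()
print("Meta-regression (mr1) is unbiased for the age-10 effect with ~95%")
print("coverage; fixed-effect MA is biased by slope x (mean age - 10) and")
print("its CI essentially never covers the age-10 truth.")
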