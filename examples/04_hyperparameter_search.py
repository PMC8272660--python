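"""Tune LS twin SVM hyperparameters with PSO and a quantum GA.

Fitness is stratified cross-validation accuracy of the classifier built at
each candidate point (costs c1, c2 and rbf gamma, searched on log scales).
Budgets here are scaled down from the reference 300-iteration setting so
the example runs in seconds; both optimizers should reach similar fitness.
"""

import numpy as np

import eegtwin as et

config = et.SimulationConfig(n_trials_per_class=50, n_channels=8,
                             erd_depth=0.5, seed=11)
epochs = et.generate_subject(config, subject_index=0)
mu = et.bandpass(epochs, (8, 12))
features = et.csp_features(et.fit_csp(mu), mu)

space = et.classifier_search_space("rbf")


def factory(params):
    return et.LSTwinSVMClassifier(
        c1=params["c1"], c2=params["c2"],
        kernel=et.KernelSpec("rbf", gamma=params["gamma"]))


def fitness(params):
    return et.cv_fitness(params, features, factory, folds=5, seed=0)


for algo in ("pso", "qga"):
    cfg = et.OptimizerConfig(algorithm=algo, max_iterations=15,
                             population=10, seed=1)
    result = et.optimize(fitness, space, cfg)
    best = {k: round(v, 4) for k, v in result.best_params.items()}
    print(f"{algo.upper():4s}: best 5-fold CV accuracy {result.best_fitness:.3f} "
          f"at {best} ({result.evaluations} evaluations)")
print("\nThe fitness trace is best-so-far, hence non-decreasing; ties between "
      "parameter settings are common once accuracy saturates.")
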