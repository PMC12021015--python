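"""Reference experiments on the synthetic exact-energy test bed.

These are the package's standard desk-scale study conditions: they generate
a corpus from the additive energy oracle, fit the stability network under a
fixed protocol, and report held-out quality.  Two experiments are defined:

* **Recovery** — can the network recover the generating energy?  A corpus of
  5 000 mutations (4 000 train / 1 000 test, lengths 30-80, mixed edit
  profile, one-hot node features) is fitted with the default architecture;
  held-out mutations of the training proteins are scored.  Run once with a
  singleton-only energy (every mutation's ddG is a sum of per-residue terms,
  exactly representable by the architecture) and once with the full
  contact-pair energy.
* **Learned antisymmetry** — does antisymmetric augmentation teach the
  unconstrained (concatenation-combiner) model that reversing a mutation
  flips the sign of ddG?  Matched models are trained on augmented and on
  direct-only data at an identical optimisation budget, over several seeds,
  and audited on held-out direct/inverse pairs via r_d-i and <delta>.

Training uses a record-level validation split for early stopping: the
deployment target here is unseen mutations of the training scaffolds, so
validation must be drawn from the same regime (protein-grouped splits, used
for cross-validation, measure transfer to unseen scaffolds instead).
"""

from __future__ import annotations

import numpy as np

from .evaluation import antisymmetry_metrics, regression_metrics
from .network import ModelConfig, predict_many
from .synthetic import (
    SyntheticEnergyModel,
    augment_samples,
    build_samples,
    generate_dataset,
)
from .training import TrainConfig, train

#: optimisation protocol for the reference experiments
RECOVERY_TRAIN = dict(max_epochs=100, patience=20, batch_size=32, learning_rate=3e-3)
ANTISYM_TRAIN = dict(max_epochs=30, patience=29, batch_size=32, learning_rate=3e-3)


def _record_split(samples, n_val, seed):
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(samples))
    return [samples[i] for i in idx[n_val:]], [samples[i] for i in idx[:n_val]]


def recovery_benchmark(
    pair_scale: float,
    seed: int = 0,
    n_train: int = 4000,
    n_test: int = 1000,
    config: ModelConfig | None = None,
) -> dict:
    """Held-out recovery of a synthetic energy by the default network.

    Returns held-out PCC/RMSE plus the corpus ddG standard deviation.
    """
    energy = SyntheticEnergyModel.random(seed=seed, pair_scale=pair_scale)
    records = generate_dataset(n_train + n_test, model=energy, seed=seed)
    samples = build_samples(records[:n_train])
    test = build_samples(records[n_train:])
    cfg = config or ModelConfig(seed=seed)
    trn, val = _record_split(samples, max(1, n_train // 10), seed)
    params, fold = train(trn, cfg, TrainConfig(seed=seed, **RECOVERY_TRAIN), val)
    report = regression_metrics(predict_many(test, params, cfg), np.array([s.ddg for s in test]))
    return {
        "pcc": report.pcc,
        "rmse": report.rmse,
        "n": report.n,
        "epochs": len(fold.history),
        "ddg_sd": float(np.std([r.record.ddg for r in records])),
    }


def _paired_antisymmetry(params, cfg, test_pairs):
    direct = [s for s in test_pairs if s.direction == "direct"]
    inverse_of = {s.pair_id: s for s in test_pairs if s.direction == "inverse"}
    inverse = [inverse_of[s.pair_id] for s in direct]
    pd_ = predict_many(direct, params, cfg)
    pi_ = predict_many(inverse, params, cfg)
    return antisymmetry_metrics(pd_, pi_)


def antisymmetry_benchmark(
    seed: int = 0,
    n_seeds: int = 3,
    n_train: int = 1600,
    n_test: int = 400,
    config: ModelConfig | None = None,
) -> dict:
    """Learned antisymmetry: augmented vs direct-only training, matched budget.

    The singleton-only energy is used so regression error does not confound
    the antisymmetry audit.  Returns per-seed and mean r_d-i / <delta> for
    both arms, plus the test ddG standard deviation.
    """
    rows = []
    for k in range(n_seeds):
        s = seed + k
        energy = SyntheticEnergyModel.random(seed=s, pair_scale=0.0)
        records = generate_dataset(n_train + n_test, model=energy, seed=s)
        train_direct = build_samples(records[:n_train])
        test_pairs = augment_samples(build_samples(records[n_train:]))
        tcfg = TrainConfig(seed=s, **ANTISYM_TRAIN)

        arms = {}
        for name, train_set in (
            ("augmented", augment_samples(train_direct)),
            ("direct_only", train_direct),
        ):
            cfg = config or ModelConfig(seed=s)
            trn, val = _record_split(train_set, max(1, len(train_set) // 10), s)
            params, _ = train(trn, cfg, tcfg, val)
            r, delta = _paired_antisymmetry(params, cfg, test_pairs)
            arms[name] = {"r_d_i": r, "delta_mean": delta}
        rows.append(
            {
                "seed": s,
                "ddg_sd": float(np.std([x.ddg for x in test_pairs])),
                **{f"{arm}_{k2}": v for arm, d in arms.items() for k2, v in d.items()},
            }
        )
    out = {"per_seed": rows}
    for key in ("augmented_r_d_i", "augmented_delta_mean", "direct_only_r_d_i", "ddg_sd"):
        out["mean_" + key] = float(np.mean([r[key] for r in rows]))
    return out
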