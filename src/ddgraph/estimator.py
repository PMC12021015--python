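"""Model/Results front end for the stability network.

`StabilityModel` is constructed from data (a list of :class:`GraphSample`
pairs, or synthetic records via :meth:`StabilityModel.from_synthetic`), holds
the architecture configuration, and `fit()` returns a
:class:`StabilityResults` carrying the fitted parameters, the per-epoch
training trace, held-out metrics and a `summary()` table — the same shape as
the classic statistical-modelling packages, so a fitted stability model can
be inspected, reused and serialised like any regression result.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import network as net
from . import training as tr
from .evaluation import EvalReport, antisymmetry_metrics, regression_metrics
from .graphs import GraphSample
from .network import ModelConfig, ModelParams
from .training import FoldResult, TrainConfig


class StabilityModel:
    """A shared-weight dual-graph ddG regressor bound to a dataset."""

    def __init__(self, samples: Sequence[GraphSample], config: ModelConfig | None = None):
        if not samples:
            raise ValueError("need at least one sample")
        self.samples = list(samples)
        self.config = config or ModelConfig()
        self.in_dim = samples[0].wild.feature_dim

    @classmethod
    def from_synthetic(
        cls,
        records,
        config: ModelConfig | None = None,
        cutoff: float | None = None,
        augment: bool = True,
    ) -> "StabilityModel":
        """Build from :class:`ddgraph.synthetic.SyntheticRecord` objects."""
        from .synthetic import augment_samples, build_samples

        kwargs = {} if cutoff is None else {"cutoff": cutoff}
        samples = build_samples(records, **kwargs)
        if augment:
            samples = augment_samples(samples)
        return cls(samples, config=config)

    def _split(
        self, val_fraction: float, seed: int, by: str = "protein"
    ) -> tuple[list[GraphSample], list[GraphSample]]:
        """Train/validation split, grouped by protein or drawn per record.

        Protein grouping measures transfer to unseen wild-type scaffolds;
        a record-level split matches the setting where held-out mutations of
        the training proteins are the prediction target.
        """
        rng = np.random.default_rng(seed)
        if by == "protein":
            proteins = sorted({s.protein_id for s in self.samples})
            shuffled = list(rng.permutation(proteins))
            n_val = max(1, int(round(val_fraction * len(proteins))))
            val_proteins = set(shuffled[:n_val])
            train = [s for s in self.samples if s.protein_id not in val_proteins]
            val = [s for s in self.samples if s.protein_id in val_proteins]
        elif by == "record":
            idx = rng.permutation(len(self.samples))
            n_val = max(1, int(round(val_fraction * len(self.samples))))
            val = [self.samples[i] for i in idx[:n_val]]
            train = [self.samples[i] for i in idx[n_val:]]
        else:
            raise ValueError("val_split must be 'protein' or 'record'")
        return train, val

    def fit(
        self,
        tcfg: TrainConfig | None = None,
        val_samples: Sequence[GraphSample] | None = None,
        val_fraction: float = 0.1,
        val_split: str = "protein",
    ) -> "StabilityResults":
        """Train once; validation comes from ``val_samples`` or a split of
        the bound dataset (grouped by protein by default)."""
        tcfg = tcfg or TrainConfig()
        if val_samples is None:
            train_set, val_set = self._split(val_fraction, tcfg.seed, val_split)
        else:
            train_set, val_set = self.samples, list(val_samples)
        params, fold = tr.train(train_set, self.config, tcfg, val_set)
        return StabilityResults(
            model=self, params=params, config=self.config, tcfg=tcfg, fold_results=[fold]
        )

    def fit_cv(self, tcfg: TrainConfig | None = None) -> tuple[list[FoldResult], dict[str, float]]:
        """Protein-grouped k-fold cross-validation of the bound dataset."""
        tcfg = tcfg or TrainConfig()
        return tr.cross_validate(self.samples, self.config, tcfg)

    def grid_search(
        self, grid: Mapping[str, Sequence], tcfg: TrainConfig | None = None
    ) -> tuple[ModelConfig, list[dict]]:
        tcfg = tcfg or TrainConfig()
        return tr.grid_search(self.samples, grid, tcfg, base_cfg=self.config)


@dataclass
class StabilityResults:
    """Fitted parameters plus training diagnostics."""

    model: StabilityModel | None
    params: ModelParams
    config: ModelConfig
    tcfg: TrainConfig | None = None
    fold_results: list[FoldResult] = field(default_factory=list)

    # -- inference ---------------------------------------------------------
    def predict(self, samples: Sequence[GraphSample]) -> np.ndarray:
        return net.predict_many(samples, self.params, self.config)

    def predict_pair(self, wild, mut) -> float:
        return net.predict_ddg(wild, mut, self.params, self.config)

    # -- diagnostics -------------------------------------------------------
    def evaluate(self, samples: Sequence[GraphSample]) -> EvalReport:
        pred = self.predict(samples)
        obs = np.array([s.ddg for s in samples])
        return regression_metrics(pred, obs)

    def antisymmetry(self, samples: Sequence[GraphSample]) -> tuple[float, float]:
        """r_d-i and <delta> over direct/inverse pairs (matched by pair_id)."""
        direct = {s.pair_id: s for s in samples if s.direction == "direct"}
        inverse = {s.pair_id: s for s in samples if s.direction == "inverse"}
        keys = sorted(set(direct) & set(inverse))
        if not keys:
            raise ValueError("no paired direct/inverse samples found")
        pd_ = self.predict([direct[k] for k in keys])
        pi_ = self.predict([inverse[k] for k in keys])
        return antisymmetry_metrics(pd_, pi_)

    def history_frame(self) -> pd.DataFrame:
        rows = []
        for fr in self.fold_results:
            for h in fr.history:
                rows.append({"fold": fr.fold, **h})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        fr = self.fold_results[0] if self.fold_results else None
        lines = [
            "Stability network regression results",
            "=" * 52,
            f"conv type        {self.config.conv_type}"
            + ("" if self.config.use_edge_weights else " (unweighted)"),
            f"conv layers      {self.config.n_conv_layers}   hidden dim {self.config.hidden_dim}",
            f"weights shared   {self.config.share_weights}   combiner {self.config.combiner}",
            f"head blocks      {self.config.head_blocks}   dropout {self.config.dropout}",
            f"parameters       {net.count_parameters(self.params)}"
            f" (conv {net.count_parameters(self.params, 'enc')})",
        ]
        if fr is not None and fr.history:
            best = fr.history[fr.best_epoch]
            lines += [
                "-" * 52,
                f"epochs trained   {len(fr.history)}   best epoch {fr.best_epoch}",
                f"train RMSE       {best['train_rmse']:.4f} kcal/mol   PCC {best['train_pcc']:.4f}",
                f"val   RMSE       {best['val_rmse']:.4f} kcal/mol   PCC {best['val_pcc']:.4f}",
            ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        in_dim = self.model.in_dim if self.model is not None else next(
            iter(self.params.values())
        ).value.shape[0]
        net.save_checkpoint(path, self.params, self.config, in_dim)

    @classmethod
    def load(cls, path: str | Path) -> "StabilityResults":
        params, config, _ = net.load_checkpoint(path)
        return cls(model=None, params=params, config=config)
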