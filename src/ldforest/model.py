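"""Model/Results interface over the forest construction.

`CFHLC` holds the data and the tuning parameters; `fit()` runs the
construction and returns a `CFHLCResults` carrying the forest, the imputed
latent data, the evaluation metrics and a text summary.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from . import metrics as met
from .build import CfhlcConfig, cfhlc
from .data import Coding, SnpMatrix
from .lcm import EmConfig


class CFHLC:
    """Forest-of-hierarchical-latent-class-models learner for SNP matrices.

    Parameters
    ----------
    data : SnpMatrix, DataFrame or ndarray
        n individuals × p markers, {0,1,2} genotypes or {0,1} haplotypes.
    coding : Coding or str
        Required when ``data`` is not already a SnpMatrix.
    window_size, t, a, b, card_max, t_cast, mi_quantile, imputation_mode,
    n_restarts, max_iter, tol, seed
        Construction parameters; see :class:`ldforest.build.CfhlcConfig`.

    Examples
    --------
    >>> from ldforest import CFHLC
    >>> res = CFHLC(matrix, seed=7).fit()      # doctest: +SKIP
    >>> res.drr, res.tree_count                # doctest: +SKIP
    """

    def __init__(self, data, coding=None, *, window_size: int = 100,
                 t: float = 0.3, a: float = 0.2, b: float = 2.0,
                 card_max: int = 20, t_cast: float = 0.95,
                 mi_quantile: float = 0.95, imputation_mode: str = "map",
                 n_restarts: int = 3, max_iter: int = 500, tol: float = 1e-6,
                 seed: int = 0):
        if isinstance(data, SnpMatrix):
            self.data = data
        else:
            if coding is None:
                raise ValueError("coding is required for raw array input")
            names = (list(data.columns)
                     if isinstance(data, pd.DataFrame) else None)
            self.data = SnpMatrix(np.asarray(data), Coding(coding),
                                  marker_names=names or [])
        self.config = CfhlcConfig(
            window_size=window_size, t=t, a=a, b=b, card_max=card_max,
            t_cast=t_cast, mi_quantile=mi_quantile,
            imputation_mode=imputation_mode,
            em=EmConfig(n_restarts=n_restarts, max_iter=max_iter, tol=tol),
            seed=seed)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, coding, **kwargs) -> "CFHLC":
        return cls(df, coding=coding, **kwargs)

    def fit(self) -> "CFHLCResults":
        """Run the construction and return the results object."""
        forest, diagnostics = cfhlc(self.data, self.config)
        return CFHLCResults(self, forest, diagnostics)


class CFHLCResults:
    """Learned forest plus its evaluation metrics."""

    def __init__(self, model: CFHLC, forest, diagnostics: list[dict]):
        self.model = model
        self.forest = forest
        self.diagnostics = diagnostics

    # -- headline quantities -------------------------------------------

    @property
    def data(self) -> SnpMatrix:
        return self.model.data

    @property
    def imputed(self) -> pd.DataFrame | None:
        """Imputed latent values, n × number of latent variables."""
        return self.forest.imputed

    @property
    def n_latent(self) -> int:
        return len(self.forest.latent_ids)

    @property
    def tree_count(self) -> int:
        return self.forest.tree_count()

    @property
    def max_layer(self) -> int:
        return self.forest.max_layer()

    @property
    def drr(self) -> float:
        """Dimension reduction rate: roots / SNPs."""
        return met.dimension_reduction_rate(self.forest)

    @property
    def reduction_percent(self) -> float:
        """Percentage of variables removed: 100·(1 − DRR)."""
        return 100.0 * (1.0 - self.drr)

    def ecr(self) -> float:
        """Entropy compression rate of the tree-leaf partition."""
        return met.entropy_compression_rate(
            met.forest_grouping(self.forest), self.data)

    def mrca_levels(self) -> met.MrcaMatrix:
        return met.mrca_levels(self.forest)

    def layer_statistics(self) -> pd.DataFrame:
        return met.layer_statistics(self.forest, self.data)

    def median_r2_by_mrca_level(self) -> pd.Series:
        return met.median_r2_by_mrca_level(self.forest, self.data)

    def metrics(self) -> dict:
        return {
            "n_snps": len(self.forest.observed_ids),
            "n_latent": self.n_latent,
            "tree_count": self.tree_count,
            "max_layer": self.max_layer,
            "drr": self.drr,
            "ecr": self.ecr(),
            "reduction_percent": self.reduction_percent,
        }

    # -- presentation ----------------------------------------------------

    def summary(self) -> str:
        m = self.metrics()
        cfg = self.model.config
        lines = [
            "Forest of hierarchical latent class models",
            "=" * 48,
            f"{'Individuals:':<28}{self.data.n}",
            f"{'Observed SNPs:':<28}{m['n_snps']}",
            f"{'Coding:':<28}{self.data.coding.value}",
            f"{'Windows:':<28}{len(self.diagnostics)} (size {cfg.window_size})",
            f"{'Latent variables:':<28}{m['n_latent']}",
            f"{'Trees (roots):':<28}{m['tree_count']}",
            f"{'Max layer:':<28}{m['max_layer']}",
            f"{'Dimension reduction rate:':<28}{m['drr']:.3f}",
            f"{'Entropy compression rate:':<28}{m['ecr']:.3f}",
            f"{'Variables removed:':<28}{m['reduction_percent']:.1f}%",
            "-" * 48,
            f"t={cfg.t}, a={cfg.a}, b={cfg.b}, card_max={cfg.card_max}, "
            f"t_cast={cfg.t_cast}, q={cfg.mi_quantile}, "
            f"impute={cfg.imputation_mode}, seed={cfg.seed}",
        ]
        per_layer = self.layer_statistics()
        lines.append("-" * 48)
        lines.append("layer  n_variables  mean_scaled_mi")
        for _, row in per_layer.iterrows():
            smi = ("-" if np.isnan(row.mean_scaled_mi)
                   else f"{row.mean_scaled_mi:.3f}")
            lines.append(f"{int(row.layer):>5}  {int(row.n_variables):>11}  {smi:>14}")
        return "\n".join(lines)

    def save(self, prefix) -> dict[str, Path]:
        """Write forest (JSON + GraphML) and imputed latent data next to ``prefix``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "forest_json": prefix.with_suffix(".forest.json"),
            "forest_graphml": prefix.with_suffix(".forest.graphml"),
            "imputed": prefix.with_suffix(".imputed.tsv"),
        }
        fio.write_forest(self.forest, paths["forest_json"], "json")
        fio.write_forest(self.forest, paths["forest_graphml"], "graphml")
        fio.write_imputed(self.forest, paths["imputed"])
        return paths
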