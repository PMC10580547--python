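"""Model/Results interface for the LDA-value fit.

:class:`LDAValueModel` wraps the full estimation chain -- min-max
normalization, hyperspherical representation, GA axis search, relevance
filtering, and a second GA pass on the surviving features -- behind a
statsmodels-style ``model.fit() -> results`` API.  The results object
carries the optimized axis, the per-participant LDA-values, the
separability trace and the relevant-feature mask, and offers the group
statistics and plots that are typically reported with the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lda import (
    GAConfig,
    GAInternals,
    normalize_columns,
    relevance_filter,
    run_ga,
    separability_ez,
    to_hyperspherical,
)


class LDAValueModel:
    """One-dimensional aging-score model over a reduced feature matrix.

    Parameters
    ----------
    features : DataFrame
        Participant-level feature matrix (rows = participants, columns =
        named features), already reduced (complete, no redundant columns).
    groups : array-like
        Class label per participant, ordered by age (e.g. 1..8).
    ages : array-like, optional
        Participant ages in years; enables the age-correlation diagnostics.
    config : GAConfig, optional
        GA hyperparameters; defaults are the production settings
        (50 000 epochs, 50 axes, p_mut 0.1, p_cross 0.8).
    """

    def __init__(self, features: pd.DataFrame, groups, ages=None, config: GAConfig | None = None):
        self.features = features
        self.groups = np.asarray(groups)
        if self.groups.size != features.shape[0]:
            raise ValueError("groups length must match the number of rows")
        self.ages = None if ages is None else np.asarray(ages, dtype=float)
        if self.ages is not None and self.ages.size != features.shape[0]:
            raise ValueError("ages length must match the number of rows")
        self.config = config or GAConfig()

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        group_col: str = "group",
        age_col: str | None = "age",
        config: GAConfig | None = None,
    ) -> "LDAValueModel":
        """Build from one DataFrame holding features plus label columns."""
        meta = [group_col] + ([age_col] if age_col and age_col in df.columns else [])
        features = df.drop(columns=meta)
        ages = df[age_col].to_numpy() if age_col and age_col in df.columns else None
        return cls(features, df[group_col].to_numpy(), ages=ages, config=config)

    def fit(self, seed: int | None = None, epochs: int | None = None) -> "LDAValueResults":
        """Run the full estimation chain and return the results.

        ``seed``/``epochs`` override the corresponding config fields for
        this fit only.  The fit is deterministic given the seed.
        """
        cfg = self.config
        if seed is not None or epochs is not None:
            cfg = replace(
                cfg,
                seed=cfg.seed if seed is None else seed,
                epochs=cfg.epochs if epochs is None else epochs,
            )
        rng = np.random.default_rng(cfg.seed)

        C = normalize_columns(self.features)
        p, theta = to_hyperspherical(C.to_numpy())
        first = run_ga(p, theta, self.groups, cfg, rng)

        mask, relevance = relevance_filter(C, self.groups, first.best_axis, cfg)
        C_rel = C.loc[:, mask]
        if C_rel.shape[1] < 2:
            # a single surviving feature has no angular representation;
            # fall back to the full set
            C_rel, mask = C, np.ones(C.shape[1], dtype=bool)
        p2, theta2 = to_hyperspherical(C_rel.to_numpy())
        final = run_ga(p2, theta2, self.groups, cfg, rng)

        values = final.projections
        # orientation convention: the score increases with group index
        # (groups are ordered by age); E_z is sign-blind
        sign = 1.0
        codes = pd.factorize(self.groups, sort=True)[0].astype(float)
        if np.corrcoef(values, codes)[0, 1] < 0:
            sign = -1.0
        lda_values = pd.Series(
            sign * values, index=self.features.index, name="lda_value"
        )
        return LDAValueResults(
            model=self,
            config=cfg,
            lda_values=lda_values,
            sign=sign,
            best_axis=final.best_axis,
            ez_best=final.best_ez,
            ez_trace=final.ez_trace,
            relevant_mask=pd.Series(mask, index=self.features.columns, name="relevant"),
            relevance=pd.Series(relevance, index=self.features.columns, name="relevance"),
            first_pass=first,
            final_pass=final,
        )


@dataclass
class LDAValueResults:
    """Fitted axis, per-participant LDA-values and diagnostics."""

    model: LDAValueModel
    config: GAConfig
    lda_values: pd.Series
    sign: float
    best_axis: np.ndarray
    ez_best: float
    ez_trace: np.ndarray
    relevant_mask: pd.Series
    relevance: pd.Series
    first_pass: GAInternals = field(repr=False, default=None)
    final_pass: GAInternals = field(repr=False, default=None)

    @property
    def relevant_features(self) -> list[str]:
        return list(self.relevant_mask.index[self.relevant_mask])

    @property
    def n_relevant(self) -> int:
        return int(self.relevant_mask.sum())

    def age_correlation(self) -> tuple[float, float]:
        """Pearson r (and p-value) between the LDA-value and age."""
        from .stats import age_correlation

        if self.model.ages is None:
            raise ValueError("model was built without ages")
        return age_correlation(self.lda_values.to_numpy(), self.model.ages)

    def pairwise_group_tests(self, alpha: float = 0.05):
        """Kruskal-Wallis omnibus + Bonferroni-corrected pairwise tests."""
        from .stats import pairwise_group_test

        return pairwise_group_test(
            self.lda_values.to_numpy(), self.model.groups, alpha=alpha
        )

    def group_means(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"lda_value": self.lda_values.to_numpy(), "group": self.model.groups}
        )
        return df.groupby("group")["lda_value"].agg(["mean", "std", "count"])

    def plot_age_relationship(self, ax=None):
        """Scatter of LDA-value vs age with the least-squares line."""
        import matplotlib.pyplot as plt

        if self.model.ages is None:
            raise ValueError("model was built without ages")
        if ax is None:
            _, ax = plt.subplots()
        x = self.model.ages
        y = self.lda_values.to_numpy()
        ax.scatter(x, y, c=self.model.groups, cmap="viridis", s=25)
        b, a = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, a + b * xs, "k--", lw=1)
        ax.set_xlabel("age (years)")
        ax.set_ylabel("LDA-value")
        return ax

    def summary(self) -> str:
        lines = [
            "LDA-value fit",
            "=" * 46,
            f"participants            {len(self.lda_values):>10d}",
            f"features in             {self.model.features.shape[1]:>10d}",
            f"relevant features       {self.n_relevant:>10d}",
            f"GA epochs               {self.config.epochs:>10d}",
            f"population size         {self.config.s:>10d}",
            f"separability E_z        {self.ez_best:>10.4f}",
        ]
        if self.model.ages is not None:
            r, pval = self.age_correlation()
            lines.append(f"Pearson r (age)         {r:>10.4f}")
            lines.append(f"  p-value               {pval:>10.3g}")
        lines.append("-" * 46)
        lines.append("group means (LDA-value)")
        gm = self.group_means()
        for g, row in gm.iterrows():
            lines.append(
                f"  group {g}:  mean {row['mean']:>12.4g}  sd {row['std']:>10.3g}  n {int(row['count']):>3d}"
            )
        return "\n".join(lines)


def estimate_lda_value(
    features: pd.DataFrame,
    groups,
    ages=None,
    config: GAConfig | None = None,
    seed: int | None = None,
    epochs: int | None = None,
) -> LDAValueResults:
    """Convenience wrapper: build an :class:`LDAValueModel` and fit it."""
    return LDAValueModel(features, groups, ages=ages, config=config).fit(
        seed=seed, epochs=epochs
    )
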