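"""Results object returned by :meth:`PsychDistressModel.fit`."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .sampling import PosteriorSamples

__all__ = ["PsychDistressResults"]


class PsychDistressResults:
    """Posterior estimates, uncertainties and diagnostics for one fit.

    Thin object-oriented surface over :mod:`distressdyn.analysis`; the
    underlying draws are available as ``.samples`` (chain-structured) and
    ``.draws_dataframe`` (flat).
    """

    def __init__(self, model, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    @property
    def draws_dataframe(self) -> pd.DataFrame:
        return self.samples.to_dataframe()

    @property
    def diagnostics(self) -> pd.DataFrame:
        return self.samples.diagnostics

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Per-parameter posterior mean, sd, median, CrI, R-hat and ESS."""
        flat = self.samples.flat
        rows = []
        tail = (1 - level) / 2
        for j, name in enumerate(self.samples.names):
            x = flat[:, j]
            lo, hi = np.quantile(x, [tail, 1 - tail])
            diag = self.samples.diagnostics.loc[name]
            rows.append(
                {
                    "parameter": name,
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "median": np.median(x),
                    f"ci{level * 100:g}_low": lo,
                    f"ci{level * 100:g}_high": hi,
                    "rhat": diag["rhat"],
                    "ess_bulk": diag["ess_bulk"],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def __str__(self) -> str:
        pinned = self.samples.meta.get("constrained") or {}
        head = (
            f"PsychDistressResults: {self.samples.n_chains} chains, "
            f"{self.samples.n_draws} retained draws"
            + (f", pinned {pinned}" if pinned else "")
        )
        return head + "\n" + self.summary().to_string(float_format=lambda v: f"{v:.6g}")

    # -- post-processing ------------------------------------------------------

    def posterior_probability(self, predicate) -> float:
        return analysis.posterior_probability(self.samples, predicate)

    def credible_interval(self, name: str, level: float = 0.95):
        return analysis.credible_interval(self.samples.marginal(name), level)

    def trajectory_bands(self, **kwargs):
        return analysis.trajectory_bands(self.samples, **kwargs)

    def counterfactual(self, **kwargs) -> analysis.CounterfactualResult:
        return analysis.counterfactual_prevalence(self.samples, **kwargs)

    def ppc(self, stream: str, **kwargs) -> analysis.PpcResult:
        return analysis.posterior_predictive_check(
            self.samples, self.model.observations, stream, **kwargs
        )

    def stream_log_likelihoods(self, **kwargs) -> pd.DataFrame:
        return analysis.stream_log_likelihoods(
            self.samples, self.model.observations, **kwargs
        )

    def save(self, outdir) -> dict:
        """Write draws CSV, run-log JSON and summary CSV; return the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "draws": outdir / "posterior.csv",
            "runlog": outdir / "runlog.json",
            "summary": outdir / "summary.csv",
        }
        self.samples.to_csv(paths["draws"], runlog_path=paths["runlog"])
        self.summary().to_csv(paths["summary"])
        return paths
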