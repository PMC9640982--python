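"""Permutation-test result container shared by topology and subnetwork tests.

Empirical p-values use the add-one estimator (1 + #extreme)/(1 + n_iter),
which can never be exactly zero; a normal-tail p derived from the z-score
is reported alongside, since resolution below 1/(n_iter+1) is otherwise
unreachable.

Several of the statistics (ECDF differences, component sizes, hub counts)
are integer-valued, and counting null ties as extreme makes the add-one
estimator conservative.  A randomized p-value — ties broken by a single
uniform draw from the test's own seeded generator — is therefore also
reported; it is exactly uniform under the null (the classical construction
for discrete permutation statistics) and is the value to use when nominal
type-I error matters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = ["PermutationResult", "write_permutation_report"]

_SIDES = ("greater", "less", "two-sided")


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic against a label-resampling null.

    ``z_score`` is None (flagged undefined) when the null is degenerate
    (zero standard deviation).
    """

    statistic: str
    observed: float
    null_values: np.ndarray
    side: str
    seed: int | None
    tie_u: float | None = None  # uniform draw for randomized tie-breaking

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}, got {self.side!r}")
        object.__setattr__(self, "null_values", np.asarray(self.null_values, dtype=float))
        if self.null_values.ndim != 1 or self.null_values.size == 0:
            raise ValueError("null_values must be a non-empty 1-D array")

    @property
    def n_iter(self) -> int:
        return int(self.null_values.size)

    @property
    def null_mean(self) -> float:
        return float(self.null_values.mean())

    @property
    def null_sd(self) -> float:
        return float(self.null_values.std(ddof=1)) if self.n_iter > 1 else 0.0

    @property
    def z_score(self) -> float | None:
        sd = self.null_sd
        if sd == 0:
            return None
        return (self.observed - self.null_mean) / sd

    @property
    def p_empirical(self) -> float:
        null, obs = self.null_values, self.observed
        if self.side == "greater":
            extreme = int((null >= obs).sum())
        elif self.side == "less":
            extreme = int((null <= obs).sum())
        else:
            mu = self.null_mean
            extreme = int((np.abs(null - mu) >= abs(obs - mu)).sum())
        return (1 + extreme) / (1 + self.n_iter)

    @property
    def p_randomized(self) -> float | None:
        """Exact-size randomized p: ties weighted by the stored uniform draw."""
        if self.tie_u is None:
            return None
        null, obs = self.null_values, self.observed
        if self.side == "greater":
            harder, ties = int((null > obs).sum()), int((null == obs).sum())
        elif self.side == "less":
            harder, ties = int((null < obs).sum()), int((null == obs).sum())
        else:
            mu = self.null_mean
            d, dobs = np.abs(null - mu), abs(obs - mu)
            harder, ties = int((d > dobs).sum()), int((d == dobs).sum())
        return (harder + self.tie_u * (1 + ties)) / (1 + self.n_iter)

    @property
    def p_normal(self) -> float | None:
        """Normal-tail p from the z-score; None when z is undefined."""
        z = self.z_score
        if z is None:
            return None
        if self.side == "greater":
            return float(stats.norm.sf(z))
        if self.side == "less":
            return float(stats.norm.cdf(z))
        return float(2 * stats.norm.sf(abs(z)))

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z_score": self.z_score,
            "p_empirical": self.p_empirical,
            "p_randomized": self.p_randomized,
            "p_normal": self.p_normal,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "side": self.side,
        }

    def summary(self) -> str:
        z = self.z_score
        ztxt = f"{z:.3f}" if z is not None else "undefined (degenerate null)"
        return (
            f"{self.statistic}: observed={self.observed:.4g}, "
            f"null={self.null_mean:.4g}±{self.null_sd:.4g}, z={ztxt}, "
            f"p_emp={self.p_empirical:.4g} ({self.side}, {self.n_iter} iterations)"
        )


def write_permutation_report(
    result: PermutationResult, tsv_path: str | Path, json_path: str | Path | None = None
) -> None:
    """Write a one-row TSV summary and optionally a JSON with the same fields."""
    d = result.to_dict()
    keys = list(d)
    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(keys) + "\n")
        fh.write("\t".join("" if d[k] is None else repr(d[k]) if isinstance(d[k], float) else str(d[k]) for k in keys) + "\n")
    if json_path is not None:
        with open(json_path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")
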