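"""Bin-based copy-number analysis and tumor-fraction estimation.

Low-depth WGS read counts in fixed genomic bins are normalized against a
panel of normals, and a hidden Markov model over the per-bin log2 ratios
estimates the ctDNA tumor fraction t: a bin in copy-number state c has
Gaussian emission mean log2((t*c + (1-t)*2) / 2) with a shared variance, and
high self-transition probability encodes segment-scale persistence. EM
alternates forward-backward posteriors with closed-ish updates of t (1-D
bounded optimisation) and the variance, restarted from a grid of low
tumor-fraction initialisations; the restart with the best likelihood wins.
Ploidy is fixed at 2, states are capped at 4 copies, no subclonal states,
autosomes only. A sample is aneuploidy-positive when t >= 0.03.

This is an openly simplified estimator in the ichorCNA mold, at desk scale:
no GC/mappability correction (the paired generator introduces no GC bias)
and its own transition/prior parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .exceptions import ContractError

DEFAULT_NORMAL_INITS = (0.95, 0.99, 0.995, 0.999)
DEFAULT_STATES = (1, 2, 3, 4)
POSITIVITY_THRESHOLD = 0.03
DEFAULT_PON_SIZE = 124


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class BinProfile:
    """Per-bin normalized log2 ratios (NaN where masked)."""

    bins: pd.DataFrame  # chrom, start, end
    log2_ratios: np.ndarray

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.log2_ratios):
            raise ContractError("bins and log2_ratios length mismatch")

    @property
    def usable(self) -> np.ndarray:
        return ~np.isnan(self.log2_ratios)

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["log2_ratio"] = self.log2_ratios
        return out


class PanelOfNormals:
    """Per-bin median log2 reference built from control profiles only."""

    def __init__(self, bins: pd.DataFrame, median_log2: np.ndarray,
                 var_log2: np.ndarray) -> None:
        self.bins = bins.reset_index(drop=True)
        self.median_log2 = np.asarray(median_log2, dtype=float)
        self.var_log2 = np.asarray(var_log2, dtype=float)
        if not len(self.bins) == len(self.median_log2) == len(self.var_log2):
            raise ContractError("PoN arrays do not match bin grid")

    @classmethod
    def from_counts(cls, bins: pd.DataFrame,
                    count_profiles: list[np.ndarray]) -> "PanelOfNormals":
        if not count_profiles:
            raise ContractError("panel of normals needs >= 1 control profile")
        logs = []
        for counts in count_profiles:
            counts = np.asarray(counts, dtype=float)
            if len(counts) != len(bins):
                raise ContractError("control profile does not match bin grid")
            med = np.median(counts[counts > 0])
            with np.errstate(divide="ignore"):
                logs.append(np.where(counts > 0, np.log2(counts / med), np.nan))
        logs = np.vstack(logs)
        return cls(
            bins,
            np.nanmedian(logs, axis=0),
            np.nanvar(logs, axis=0, ddof=1) if len(logs) > 1 else np.zeros(len(bins)),
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.bins.copy()
        out["median_log2"] = self.median_log2
        out["var_log2"] = self.var_log2
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PanelOfNormals":
        return cls(
            df[["chrom", "start", "end"]],
            df["median_log2"].to_numpy(),
            df["var_log2"].to_numpy(),
        )


def normalize_bins(counts: pd.DataFrame, pon: PanelOfNormals) -> BinProfile:
    """log2(count / sample median) minus the PoN per-bin median.

    Bins with zero counts or without PoN coverage are masked (NaN). The
    sample-median scaling makes the result invariant to uniform depth
    changes; an all-neutral profile centers at 0.
    """
    grid_cols = ["chrom", "start", "end"]
    if not counts[grid_cols].reset_index(drop=True).equals(pon.bins[grid_cols]):
        raise ContractError("bin grid of counts does not match panel of normals")
    c = counts["count"].to_numpy(dtype=float)
    usable = (c > 0) & ~np.isnan(pon.median_log2)
    med = np.median(c[usable])
    ratios = np.full(len(c), np.nan)
    ratios[usable] = np.log2(c[usable] / med) - pon.median_log2[usable]
    return BinProfile(counts[grid_cols].reset_index(drop=True), ratios)


# ---------------------------------------------------------------------------
# the tumor-fraction HMM
# ---------------------------------------------------------------------------


def state_means(t: float, states: np.ndarray) -> np.ndarray:
    """Expected log2 ratio of each copy-number state at tumor fraction t.

    At t -> 0 all states coincide at 0 (the identity limit)."""
    return np.log2((t * states + (1.0 - t) * 2.0) / 2.0)


def _forward_backward(
    obs: np.ndarray, means: np.ndarray, var: float, trans: np.ndarray,
    start: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Scaled forward-backward; returns (posteriors, log-likelihood)."""
    n, k = len(obs), len(means)
    ll_obs = -0.5 * (np.log(2 * np.pi * var) + (obs[:, None] - means) ** 2 / var)
    b = np.exp(ll_obs - ll_obs.max(axis=1, keepdims=True))
    alpha = np.empty((n, k))
    scale = np.empty(n)
    alpha[0] = start * b[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for i in range(1, n):
        alpha[i] = (alpha[i - 1] @ trans) * b[i]
        scale[i] = alpha[i].sum()
        alpha[i] /= scale[i]
    beta = np.empty((n, k))
    beta[-1] = 1.0
    for i in range(n - 2, -1, -1):
        beta[i] = (trans @ (b[i + 1] * beta[i + 1])) / scale[i + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    loglik = float(np.log(scale).sum() + ll_obs.max(axis=1).sum())
    return gamma, loglik


def _viterbi(
    obs: np.ndarray, means: np.ndarray, var: float, trans: np.ndarray,
    start: np.ndarray,
) -> np.ndarray:
    n, k = len(obs), len(means)
    ll_obs = -0.5 * (np.log(2 * np.pi * var) + (obs[:, None] - means) ** 2 / var)
    log_trans = np.log(trans)
    delta = np.log(start) + ll_obs[0]
    back = np.zeros((n, k), dtype=np.int64)
    for i in range(1, n):
        cand = delta[:, None] + log_trans
        back[i] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + ll_obs[i]
    path = np.empty(n, dtype=np.int64)
    path[-1] = delta.argmax()
    for i in range(n - 2, -1, -1):
        path[i] = back[i + 1, path[i + 1]]
    return path


@dataclass
class TumorFractionResults:
    """Fitted tumor-fraction estimate with per-bin Viterbi states."""

    tumor_fraction: float
    positive: bool
    loglik: float
    best_normal_init: float
    states: np.ndarray  # per usable bin, integer copy number
    bin_states: pd.DataFrame  # chrom, start, end, state (NaN-masked bins = 2)
    variance: float
    converged: bool
    n_iter: int
    threshold: float
    raw_tumor_fraction: float  # EM optimum before the no-aneuploidy guard
    n_aneuploid_bins: int
    model: "TumorFractionModel" = None

    def summary(self) -> str:
        lines = [
            "Tumor fraction estimate (bin-level copy-number HMM)",
            "=" * 51,
            f"bins used                  {int(len(self.states))}",
            f"tumor fraction             {self.tumor_fraction:.4f}",
            f"positive (t >= {self.threshold:.2f})      {self.positive}",
            f"aneuploid bins (Viterbi)   {self.n_aneuploid_bins}",
            f"best normal-fraction init  {self.best_normal_init}",
            f"log-likelihood             {self.loglik:.2f}",
            f"emission variance          {self.variance:.3e}",
            f"converged                  {self.converged} ({self.n_iter} iter)",
        ]
        return "\n".join(lines)

    def segments(self) -> pd.DataFrame:
        """Merge consecutive same-state bins into segments (BED-like)."""
        df = self.bin_states
        seg_id = (
            (df["state"] != df["state"].shift())
            | (df["chrom"] != df["chrom"].shift())
        ).cumsum()
        grouped = df.groupby(seg_id, sort=False).agg(
            chrom=("chrom", "first"), start=("start", "min"),
            end=("end", "max"), state=("state", "first"),
        )
        return grouped.reset_index(drop=True)


class TumorFractionModel:
    """EM-fitted HMM over normalized log2 ratios (statsmodels-style model).

    Parameters mirror the published low-tumor-content parameterization:
    normal-fraction initialisations {0.95, 0.99, 0.995, 0.999} (i.e. t0 in
    {0.05, 0.01, 0.005, 0.001}), ploidy 2, copy-number states {1,2,3,4},
    positivity threshold 0.03. The t estimate is bounded in (0, 0.5] to keep
    EM identifiable at low tumor content.
    """

    def __init__(
        self,
        profile: BinProfile,
        states: tuple[int, ...] = DEFAULT_STATES,
        normal_inits: tuple[float, ...] = DEFAULT_NORMAL_INITS,
        self_transition: float = 0.99,
        threshold: float = POSITIVITY_THRESHOLD,
        t_max: float = 0.5,
        max_iter: int = 50,
        tol: float = 1e-3,
        min_usable_bins: int = 50,
        min_aneuploid_bins: int = 5,
    ) -> None:
        self.profile = profile
        self.states = np.asarray(states, dtype=float)
        if 2 not in states:
            raise ContractError("copy-number states must include the neutral state 2")
        self.normal_inits = tuple(normal_inits)
        self.self_transition = float(self_transition)
        self.threshold = float(threshold)
        self.t_max = float(t_max)
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.min_aneuploid_bins = int(min_aneuploid_bins)
        self.obs = profile.log2_ratios[profile.usable]
        if len(self.obs) < min_usable_bins:
            raise ContractError(
                f"need >= {min_usable_bins} usable bins, got {len(self.obs)}"
            )
        k = len(self.states)
        off = (1.0 - self.self_transition) / (k - 1)
        self.trans = np.full((k, k), off)
        np.fill_diagonal(self.trans, self.self_transition)
        # start distribution strongly favors the neutral state
        self.start = np.full(k, 0.01 / (k - 1))
        self.start[np.where(self.states == 2)[0][0]] = 0.99

    def _em(self, t0: float) -> dict:
        obs = self.obs
        t = t0
        var = max(float(np.var(obs)), 1e-8)
        loglik = -np.inf
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            means = state_means(t, self.states)
            gamma, new_loglik = _forward_backward(
                obs, means, var, self.trans, self.start
            )

            def neg_obj(tt: float) -> float:
                mu = state_means(tt, self.states)
                return float((gamma * (obs[:, None] - mu) ** 2).sum())

            res = minimize_scalar(
                neg_obj, bounds=(1e-6, self.t_max), method="bounded",
                options={"xatol": 1e-7},
            )
            t = float(res.x)
            mu = state_means(t, self.states)
            var = max(float((gamma * (obs[:, None] - mu) ** 2).sum() / len(obs)), 1e-10)
            if abs(new_loglik - loglik) < self.tol:
                loglik = new_loglik
                converged = True
                break
            loglik = new_loglik
        return {"t": t, "var": var, "loglik": loglik, "converged": converged,
                "n_iter": it}

    def fit(self) -> TumorFractionResults:
        best = None
        best_init = None
        for nf in self.normal_inits:
            fit = self._em(1.0 - nf)
            if best is None or fit["loglik"] > best["loglik"]:
                best, best_init = fit, nf
        means = state_means(best["t"], self.states)
        path = _viterbi(self.obs, means, best["var"], self.trans, self.start)
        state_cn = self.states[path].astype(int)
        n_aneuploid = int((state_cn != 2).sum())
        raw_t = best["t"]
        # no aneuploid segment -> no copy-number evidence of tumor content:
        # t is unidentifiable (the neutral state's mean is 0 for every t)
        t_hat = raw_t if n_aneuploid >= self.min_aneuploid_bins else 0.0
        full_states = np.full(len(self.profile.log2_ratios), 2, dtype=int)
        full_states[self.profile.usable] = state_cn
        bin_states = self.profile.bins.copy()
        bin_states["state"] = full_states
        return TumorFractionResults(
            tumor_fraction=t_hat,
            positive=t_hat >= self.threshold,
            loglik=best["loglik"],
            best_normal_init=best_init,
            states=state_cn,
            bin_states=bin_states,
            variance=best["var"],
            converged=best["converged"],
            n_iter=best["n_iter"],
            threshold=self.threshold,
            raw_tumor_fraction=raw_t,
            n_aneuploid_bins=n_aneuploid,
            model=self,
        )


def fit_tumor_fraction(profile: BinProfile, **kwargs) -> TumorFractionResults:
    """Convenience wrapper: build a TumorFractionModel and fit it."""
    return TumorFractionModel(profile, **kwargs).fit()
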