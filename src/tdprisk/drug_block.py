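"""Ion-channel block pharmacology: Hill dose-response curves and conductance scaling.

A drug blocks up to four measured cardiac currents (INaL, INa, ICaL, IKr).
The fractional block at free concentration ``d`` (nM) follows the Hill
equation

    inhibition(d) = 1 / (1 + (IC50 / d)**h)

with half-maximal concentration IC50 (nM) and Hill coefficient h.  The
channel's maximal conductance under drug is ``g = g_control * (1 - inhibition)``.

Uncertainty in (IC50, h) is propagated by Bayesian MCMC over replicated
dose-response measurements: :class:`HillCurveSampler` draws joint posterior
samples (2,000 per drug by default), which downstream modules convert into
per-channel block profiles at multiples of the therapeutic Cmax.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

# The four channels with in-vitro dose-response measurements.
BLOCKABLE_CHANNELS = ("INaL", "INa", "ICaL", "IKr")
# All channels carried by the cell model (the last three are never blocked).
ALL_CHANNELS = ("INa", "INaL", "ICaL", "IKr", "IKs", "IK1", "Ito")

DOSE_RESPONSE_COLUMNS = ["drug", "channel", "conc", "block", "replicate"]


class InsufficientDataError(ValueError):
    """Fewer distinct concentrations than the Hill fit requires."""


class MCMCDiagnosticWarning(UserWarning):
    """Chain acceptance rate outside the healthy range after adaptation."""


def inhibition_factor(ic50, h, d):
    """Fractional channel block at concentration ``d`` (nM).

    Evaluates ``1 / (1 + (ic50/d)**h)``; the zero-dose limit returns 0
    exactly.  Accepts scalars or arrays in ``d``.

    Parameters
    ----------
    ic50 : positive float, nM
    h : positive float, dimensionless Hill coefficient
    d : non-negative float or array, nM
    """
    if np.any(np.asarray(ic50) <= 0):
        raise ValueError(f"ic50 must be positive, got {ic50}")
    if np.any(np.asarray(h) <= 0):
        raise ValueError(f"h must be positive, got {h}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError(f"concentration d must be non-negative, got {d}")
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    out = np.zeros_like(d)
    pos = d > 0
    # (d/ic50)^h form avoids overflow of (ic50/d)^h at tiny doses
    ratio = np.power(d[pos] / ic50, h)
    out[pos] = ratio / (1.0 + ratio)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class ChannelBlockProfile:
    """Per-channel inhibition fractions in [0, 1]; absent channels mean 0."""

    inhibition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for ch, f in self.inhibition.items():
            if ch not in ALL_CHANNELS:
                raise KeyError(f"unknown channel {ch!r}")
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"inhibition[{ch}]={f} outside [0, 1]")

    def __getitem__(self, channel: str) -> float:
        return self.inhibition.get(channel, 0.0)


@dataclass(frozen=True)
class ConductanceSet:
    """Maximal conductances per channel (model units)."""

    g: dict[str, float]

    def __post_init__(self):
        for ch, v in self.g.items():
            if v < 0:
                raise ValueError(f"conductance {ch}={v} must be >= 0")

    def __getitem__(self, channel: str) -> float:
        return self.g[channel]

    def scaled(self, profile: ChannelBlockProfile) -> "ConductanceSet":
        return scale_conductances(self, profile)


def scale_conductances(g_control: ConductanceSet, profile: ChannelBlockProfile) -> ConductanceSet:
    """Apply ``g = g_control * (1 - inhibition)`` channelwise.

    Channels absent from the profile are returned unchanged.
    """
    return ConductanceSet({ch: g0 * (1.0 - profile[ch]) for ch, g0 in g_control.g.items()})


@dataclass(frozen=True)
class DrugExposure:
    """Therapeutic exposure: free Cmax (nM) and the concentration ladder."""

    drug_id: str
    cmax: float
    concentration_multipliers: tuple = (1.0, 2.0, 3.0, 4.0)
    risk_label: str | None = None

    def __post_init__(self):
        if self.cmax <= 0:
            raise ValueError(f"cmax must be positive, got {self.cmax}")
        m = self.concentration_multipliers
        if any(b <= a for a, b in zip(m, m[1:])) or any(x <= 0 for x in m):
            raise ValueError("multipliers must be positive and strictly increasing")


class HillPosteriorSample:
    """One joint posterior draw of (IC50, h) for every blocked channel of a drug."""

    __slots__ = ("drug_id", "sample_index", "params")

    def __init__(self, drug_id: str, sample_index: int, params: dict[str, tuple[float, float]]):
        for ch, (ic50, h) in params.items():
            if ch not in BLOCKABLE_CHANNELS:
                raise KeyError(f"unknown blockable channel {ch!r}")
            if ic50 <= 0 or h <= 0:
                raise ValueError(f"{ch}: ic50 and h must be positive, got ({ic50}, {h})")
        self.drug_id = drug_id
        self.sample_index = int(sample_index)
        self.params = params

    def __repr__(self):
        return f"HillPosteriorSample({self.drug_id!r}, {self.sample_index}, {self.params})"


def block_profile(sample: HillPosteriorSample, exposure: DrugExposure, multiplier: float) -> ChannelBlockProfile:
    """Per-channel inhibition at concentration ``multiplier * cmax``."""
    if multiplier not in exposure.concentration_multipliers:
        raise ValueError(
            f"multiplier {multiplier} not in exposure ladder {exposure.concentration_multipliers}"
        )
    d = multiplier * exposure.cmax
    return ChannelBlockProfile(
        {ch: float(inhibition_factor(ic50, h, d)) for ch, (ic50, h) in sample.params.items()}
    )


# ---------------------------------------------------------------------------
# Bayesian Hill fitting
# ---------------------------------------------------------------------------

_LOG_IC50_LO, _LOG_IC50_HI = np.log(1e-3), np.log(1e9)  # nM
_LOG_H_SD = 0.5          # log-normal prior on h, centred at h = 1
_SIGMA_PRIOR_SCALE = 0.1  # half-normal prior scale on observation noise sd


def _log_posterior(theta, log_d, y):
    """Unnormalised log posterior over theta = (log IC50, log h, log sigma).

    Gaussian likelihood on fractional block, log-uniform IC50, log-normal h,
    half-normal sigma.  Vectorised over leading chain axis of theta.
    """
    log_ic50, log_h, log_sigma = theta[..., 0], theta[..., 1], theta[..., 2]
    lp = np.where(
        (log_ic50 >= _LOG_IC50_LO) & (log_ic50 <= _LOG_IC50_HI), 0.0, -np.inf
    )
    lp = lp - 0.5 * (log_h / _LOG_H_SD) ** 2
    sigma = np.exp(log_sigma)
    lp = lp - 0.5 * (sigma / _SIGMA_PRIOR_SCALE) ** 2 + log_sigma  # half-normal + Jacobian
    # Hill mean at each dose: logistic in log-dose space
    z = np.exp(log_h)[..., None] * (log_d - log_ic50[..., None])
    mu = 1.0 / (1.0 + np.exp(-z))
    resid = y - mu
    n = y.shape[-1]
    ll = -n * log_sigma - 0.5 * np.sum(resid**2, axis=-1) / sigma**2
    return lp + ll


class HillCurveSampler(BaseEstimator):
    """Adaptive random-walk Metropolis sampler for Hill dose-response posteriors.

    ``fit`` consumes a tidy dose-response table and draws ``n_samples`` joint
    (IC50, h) posterior samples per (drug, channel), walking in
    (log IC50, log h, log sigma).  Four parallel chains are advanced
    simultaneously; the step scale adapts during burn-in toward ~30%
    acceptance, then freezes.  Deterministic given ``seed``.

    Parameters
    ----------
    n_samples : int, default 2000
        Posterior draws retained per (drug, channel), pooled over chains.
    n_iter : int, default 10000
        Post-adaptation iterations per chain (an equal burn-in precedes them).
    n_chains : int, default 4
    seed : int, default 0

    Attributes
    ----------
    samples_ : pandas.DataFrame
        Wide per-drug table in the interchange dialect (one row per draw,
        IC50/h columns per channel; unblocked channels are NaN).
    acceptance_ : dict[(drug, channel), float]
        Post-adaptation acceptance rates.
    diagnostics_ : list[str]
        Human-readable warnings for chains outside acceptance [0.05, 0.95].
    """

    def __init__(self, n_samples: int = 2000, n_iter: int = 10000, n_chains: int = 4, seed: int = 0):
        self.n_samples = n_samples
        self.n_iter = n_iter
        self.n_chains = n_chains
        self.seed = seed

    def fit(self, points: pd.DataFrame, y=None):
        df = validate_dose_response(points)
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        root = np.random.SeedSequence(self.seed)
        self.acceptance_ = {}
        self.diagnostics_ = []
        rows = {}
        # one child seed stream per (drug, channel), keyed deterministically
        # by sorted group order so identical tables give identical samples
        groups = sorted(df.groupby(["drug", "channel"]).groups)
        children = root.spawn(len(groups))
        grouped = df.groupby(["drug", "channel"])
        for (drug, channel), ss in zip(groups, children):
            g = grouped.get_group((drug, channel))
            ic50, h, acc = self._sample_one(
                np.log(g["conc"].to_numpy(float)), g["block"].to_numpy(float), ss
            )
            self.acceptance_[(drug, channel)] = acc
            if not (0.05 <= acc <= 0.95):
                msg = f"{drug}/{channel}: MCMC acceptance {acc:.3f} outside [0.05, 0.95]"
                self.diagnostics_.append(msg)
                warnings.warn(msg, MCMCDiagnosticWarning)
            rows.setdefault(drug, {})[channel] = (ic50, h)
        self.samples_ = _to_wide(rows, self.n_samples)
        return self

    def _sample_one(self, log_d, y, seedseq):
        n_distinct = len(np.unique(log_d))
        if n_distinct < 3:
            raise InsufficientDataError(
                f"need >= 3 distinct concentrations, got {n_distinct}"
            )
        rng = np.random.default_rng(seedseq)
        C = self.n_chains
        # crude initialisation: IC50 near the dose closest to half block
        i0 = int(np.argmin(np.abs(y - 0.5)))
        theta = np.empty((C, 3))
        theta[:, 0] = log_d[i0] + rng.normal(0, 0.5, C)
        theta[:, 1] = rng.normal(0, 0.2, C)
        theta[:, 2] = np.log(0.05) + rng.normal(0, 0.3, C)
        lp = _log_posterior(theta, log_d, y)
        scale = np.full(C, 0.3)
        n_burn = self.n_iter  # burn-in == adaptation phase, same length
        accepted = np.zeros(C)
        keep = []
        thin = max(1, (C * self.n_iter) // max(self.n_samples, 1))
        for it in range(n_burn + self.n_iter):
            prop = theta + scale[:, None] * rng.normal(size=(C, 3))
            lp_prop = _log_posterior(prop, log_d, y)
            log_u = np.log(rng.uniform(size=C))
            acc = log_u < (lp_prop - lp)
            theta[acc] = prop[acc]
            lp[acc] = lp_prop[acc]
            if it < n_burn:
                # Robbins-Monro adaptation toward 30% acceptance
                scale *= np.exp((acc.astype(float) - 0.3) / np.sqrt(it + 1.0))
                scale = np.clip(scale, 1e-3, 5.0)
            else:
                accepted += acc
                if (it - n_burn) % thin == 0:
                    keep.append(theta.copy())
        chain = np.concatenate(keep, axis=0)  # (kept*C, 3)
        acc_rate = float(np.mean(accepted) / self.n_iter)
        # pool chains, deterministically subsample/tile to exactly n_samples
        idx = np.linspace(0, len(chain) - 1, self.n_samples).round().astype(int)
        sel = chain[idx]
        return np.exp(sel[:, 0]), np.exp(sel[:, 1]), acc_rate


def _to_wide(rows, n_samples):
    out = []
    for drug in sorted(rows):
        rec = {"drug": drug, "sample": np.arange(n_samples)}
        for ch in BLOCKABLE_CHANNELS:
            if ch in rows[drug]:
                ic50, h = rows[drug][ch]
                rec[f"IC50_{ch}"] = ic50
                rec[f"h_{ch}"] = h
            else:
                rec[f"IC50_{ch}"] = np.nan
                rec[f"h_{ch}"] = np.nan
        out.append(pd.DataFrame(rec))
    cols = ["drug", "sample"] + [f"{p}_{c}" for c in BLOCKABLE_CHANNELS for p in ("IC50", "h")]
    if not out:
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)[cols]


def fit_hill_mcmc(points: pd.DataFrame, n_samples: int = 2000, seed: int = 0, **kw) -> pd.DataFrame:
    """Functional wrapper over :class:`HillCurveSampler`; returns the wide table."""
    return HillCurveSampler(n_samples=n_samples, seed=seed, **kw).fit(points).samples_


def samples_from_table(table: pd.DataFrame, drug: str) -> list[HillPosteriorSample]:
    """Materialise :class:`HillPosteriorSample` objects for one drug."""
    sub = table[table["drug"] == drug]
    if sub.empty:
        raise KeyError(f"drug {drug!r} not in Hill-sample table")
    out = []
    for _, row in sub.iterrows():
        params = {}
        for ch in BLOCKABLE_CHANNELS:
            ic50 = row.get(f"IC50_{ch}", np.nan)
            if pd.notna(ic50):
                params[ch] = (float(ic50), float(row[f"h_{ch}"]))
        out.append(HillPosteriorSample(drug, int(row["sample"]), params))
    return out


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def validate_dose_response(df: pd.DataFrame) -> pd.DataFrame:
    """Schema check for the tidy dose-response dialect (conc in nM, block as fraction)."""
    missing = set(DOSE_RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dose-response table missing columns: {sorted(missing)}")
    df = df.copy()
    df["conc"] = pd.to_numeric(df["conc"])
    df["block"] = pd.to_numeric(df["block"])
    if (df["conc"] <= 0).any():
        raise ValueError("all concentrations must be positive (nM)")
    if ((df["block"] < 0) | (df["block"] > 1)).any():
        raise ValueError("block must be a fraction in [0, 1], not a percent")
    bad = set(df["channel"]) - set(BLOCKABLE_CHANNELS)
    if bad:
        raise ValueError(f"unknown channels in dose-response table: {sorted(bad)}")
    return df


def read_dose_response(path) -> pd.DataFrame:
    return validate_dose_response(pd.read_csv(path))


def write_hill_samples(table: pd.DataFrame, path) -> None:
    """Write the wide Hill-sample dialect with 10-significant-digit decimal text."""
    table.to_csv(path, index=False, float_format="%.10g")


def read_hill_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"drug", "sample"}
    if not need <= set(df.columns):
        raise ValueError(f"Hill-sample table missing columns: {sorted(need - set(df.columns))}")
    return df


def hill_samples_roundtrip(table: pd.DataFrame) -> pd.DataFrame:
    """Serialise to the CSV dialect in memory and parse back (used by tests)."""
    buf = io.StringIO()
    write_hill_samples(table, buf)
    buf.seek(0)
    return read_hill_samples(buf)
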