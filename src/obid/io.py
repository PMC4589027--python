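"""Readers, writers and run configuration.

All interchange files are comma-separated UTF-8 text with a mandatory header
row.  Expert files hold one row per expert (integer relevance ratings 1-4);
participant files hold one row per subject (integer responses 1..C_j); prior
files carry one row per item with the elicited prior summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._mcmc import MCMCSettings
from .expert import ExpertRatings, PriorSpec
from .sampler import ParticipantResponses

__all__ = [
    "read_expert_csv",
    "read_participant_csv",
    "write_prior_csv",
    "read_prior_csv",
    "write_draws_csv",
    "RunConfig",
    "load_config",
]


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: no data rows")
    return df


def _to_int_matrix(df: pd.DataFrame, path, lo: int, hi: int | np.ndarray) -> np.ndarray:
    values = df.to_numpy()
    out = np.empty(values.shape, dtype=int)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            v = values[i, j]
            col = df.columns[j]
            if pd.isna(v):
                raise ValueError(f"{path}: missing cell at row {i + 1}, column {col!r}")
            fv = float(v)
            if fv != int(fv):
                raise ValueError(
                    f"{path}: non-integer value {v!r} at row {i + 1}, column {col!r}"
                )
            iv = int(fv)
            h = int(hi if np.isscalar(hi) else hi[j])
            if iv < lo or iv > h:
                raise ValueError(
                    f"{path}: value {iv} outside {lo}..{h} at row {i + 1}, column {col!r}"
                )
            out[i, j] = iv
    return out


def read_expert_csv(path) -> ExpertRatings:
    """Read a K x P expert relevance-rating table (integer cells 1-4)."""
    df = _read_table(path)
    x = _to_int_matrix(df, path, 1, 4)
    return ExpertRatings(x, items=list(df.columns))


def read_participant_csv(path, categories=None) -> ParticipantResponses:
    """Read an N x P participant response table.

    ``categories`` gives C_j per item (scalar or sequence); when omitted it
    is inferred as the observed per-item maximum.
    """
    df = _read_table(path)
    P = df.shape[1]
    if categories is None:
        cats = None
        hi = np.full(P, np.iinfo(np.int32).max)
    else:
        cats = np.full(P, categories, dtype=int) if np.isscalar(categories) \
            else np.asarray(categories, dtype=int)
        hi = cats
    y = _to_int_matrix(df, path, 1, hi)
    return ParticipantResponses(y, categories=cats, items=list(df.columns))


def write_prior_csv(prior: PriorSpec, path, items=None) -> None:
    """Persist per-item prior summaries (item, mu0, n0, lambda_mean, lambda_var)."""
    P = prior.n_items
    items = items or [f"item{j + 1}" for j in range(P)]
    mu0 = prior.mu0 if prior.mu0 is not None else np.full(P, np.nan)
    n0 = prior.n0 if prior.n0 is not None else np.nan
    pd.DataFrame(
        {
            "item": items,
            "mu0": np.asarray(mu0, dtype=float),
            "n0": np.full(P, n0, dtype=float),
            "lambda_mean": prior.lambda_mean,
            "lambda_var": prior.lambda_var,
            "informative": np.full(P, prior.informative),
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_prior_csv(path) -> PriorSpec:
    df = _read_table(path)
    required = {"lambda_mean", "lambda_var"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: prior file missing columns {sorted(missing)}")
    mu0 = df["mu0"].to_numpy(float) if "mu0" in df else None
    if mu0 is not None and np.all(np.isnan(mu0)):
        mu0 = None
    n0 = float(df["n0"].iloc[0]) if "n0" in df and not pd.isna(df["n0"].iloc[0]) else None
    informative = bool(df["informative"].iloc[0]) if "informative" in df else True
    return PriorSpec(
        lambda_mean=df["lambda_mean"].to_numpy(float),
        lambda_var=df["lambda_var"].to_numpy(float),
        informative=informative,
        mu0=mu0,
        n0=n0,
    )


def write_draws_csv(draws, path) -> None:
    """Flat draw file: draw, chain, parameter, value."""
    frames = []
    n_chains, n_draws, P = draws.alpha_draws.shape
    for name, arr in (("alpha", draws.alpha_draws), ("lambda", draws.lambda_draws)):
        for j in range(P):
            for ch in range(n_chains):
                frames.append(pd.DataFrame({
                    "draw": np.arange(n_draws),
                    "chain": ch,
                    "parameter": f"{name}[{draws.items[j]}]",
                    "value": arr[ch, :, j],
                }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Validated end-to-end run configuration (YAML or JSON)."""

    expert_csv: str | None = None
    participant_csv: str | None = None
    output_dir: str = "."
    scale_style: str = "cohen"
    prior_mode: str = "informative"
    seed: int | None = None
    expert_mcmc: MCMCSettings = None
    participant_mcmc: MCMCSettings = None

    def __post_init__(self):
        if self.prior_mode not in ("informative", "flat"):
            raise ValueError(
                f"prior_mode must be 'informative' or 'flat', got {self.prior_mode!r}"
            )
        if self.scale_style not in ("cohen", "equal"):
            raise ValueError(
                f"scale_style must be 'cohen' or 'equal', got {self.scale_style!r}"
            )
        if self.prior_mode == "informative" and self.expert_csv is None:
            raise ValueError("prior_mode='informative' requires expert_csv")
        if self.expert_mcmc is None:
            self.expert_mcmc = MCMCSettings(seed=self.seed)
        if self.participant_mcmc is None:
            self.participant_mcmc = MCMCSettings(seed=self.seed)
        for key in ("expert_csv", "participant_csv"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise ValueError(f"config key {key!r}: path {p!r} is not readable")


_MCMC_KEYS = {"chains", "burn_in", "iterations", "tuning", "seed"}


def _settings_from_dict(d: dict, seed) -> MCMCSettings:
    unknown = set(d) - _MCMC_KEYS
    if unknown:
        raise ValueError(f"unknown MCMC settings keys: {sorted(unknown)}")
    d = dict(d)
    d.setdefault("seed", seed)
    return MCMCSettings(**d)


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    known = {"expert_csv", "participant_csv", "output_dir", "scale_style",
             "prior_mode", "seed", "expert_mcmc", "participant_mcmc"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    seed = data.get("seed")
    for key in ("expert_mcmc", "participant_mcmc"):
        if key in data:
            if not isinstance(data[key], dict):
                raise ValueError(f"{path}: {key} must be a mapping")
            data[key] = _settings_from_dict(data[key], seed)
    return RunConfig(**data)
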