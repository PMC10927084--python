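"""Phase-diagram grids and Monte Carlo parameter sampling.

The phase diagram classifies every cell of an alpha(P_Ca) x alpha(G_Ks)
grid on a fixed background of the other scaling factors.  The Monte Carlo
scan draws the five scaling factors log-uniformly (by default) from a
multiplicative range and tabulates the mechanism composition among the
EAD-positive samples, mirroring a mechanism-frequency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (ModelParameters, control_parameters, apply_scaling,
                    integrate, SimulationDiverged, ALPHA_NAMES,
                    variant_initial_state)
from .protocols import StimulusProtocol, build_stimulus
from .dissect import run_dissection

__all__ = ["PhaseDiagramGrid", "MonteCarloResult", "phase_diagram",
           "monte_carlo", "variant_initial_state"]

@dataclass
class PhaseDiagramGrid:
    """Classified cells over the alpha(P_Ca)-alpha(G_Ks) plane."""

    pca_values: np.ndarray
    gks_values: np.ndarray
    labels: np.ndarray          # shape (n_gks, n_pca), dtype object
    background_alpha: dict
    protocol: dict

    def label_at(self, pca: float, gks: float) -> str:
        i = int(np.argmin(np.abs(self.gks_values - gks)))
        j = int(np.argmin(np.abs(self.pca_values - pca)))
        return str(self.labels[i, j])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.gks_values):
            for j, p in enumerate(self.pca_values):
                rows.append({"alpha_PCa": p, "alpha_GKs": g,
                             "label": self.labels[i, j]})
        return pd.DataFrame(rows)


def phase_diagram(pca_values: Sequence[float],
                  gks_values: Sequence[float],
                  background_alpha: Mapping[str, float] | None = None,
                  protocol: StimulusProtocol | None = None,
                  base: ModelParameters | None = None,
                  t_end: float = 10000.0,
                  dt: float = 0.01) -> PhaseDiagramGrid:
    """Classify every (alpha(P_Ca), alpha(G_Ks)) cell of a grid.

    A cell whose simulation diverges is recorded with the label
    ``"diverged"`` rather than aborting the scan.
    """
    pca_values = np.asarray(sorted(pca_values), dtype=float)
    gks_values = np.asarray(sorted(gks_values), dtype=float)
    background_alpha = dict(background_alpha or {})
    if protocol is None:
        protocol = build_stimulus("single")
    if base is None:
        base = control_parameters()
    y0 = variant_initial_state(base)
    labels = np.empty((len(gks_values), len(pca_values)), dtype=object)
    for i, g in enumerate(gks_values):
        for j, p in enumerate(pca_values):
            alpha = dict(background_alpha)
            alpha["P_Ca"] = p
            alpha["G_Ks"] = g
            params = apply_scaling(base, alpha)
            try:
                c = run_dissection(params, protocol, t_end=t_end, dt=dt,
                                   y0=y0, with_confirmatory=False)
                labels[i, j] = c.label
            except SimulationDiverged:
                labels[i, j] = "diverged"
    return PhaseDiagramGrid(pca_values=pca_values, gks_values=gks_values,
                            labels=labels,
                            background_alpha=background_alpha,
                            protocol=protocol.describe())


@dataclass
class MonteCarloResult:
    """Mechanism composition of a random parameter population."""

    seed: int
    n_samples: int
    alpha_range: tuple
    distribution: str
    flattened: bool
    samples: pd.DataFrame       # one row per sample: alphas + label
    n_ead_positive: int = 0
    n_diverged: int = 0
    fractions: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "seed": self.seed,
            "n_samples": self.n_samples,
            "alpha_range": list(self.alpha_range),
            "distribution": self.distribution,
            "fss_flattened": self.flattened,
            "n_ead_positive": self.n_ead_positive,
            "n_diverged": self.n_diverged,
            "fractions_percent": {k: 100.0 * v for k, v in self.fractions.items()},
        }


def monte_carlo(n: int = 500,
                alpha_range: tuple[float, float] = (0.1, 10.0),
                seed: int = 0,
                flattened: bool = False,
                distribution: str = "log_uniform",
                protocol: StimulusProtocol | None = None,
                t_end: float = 10000.0,
                dt: float = 0.01,
                base: ModelParameters | None = None) -> MonteCarloResult:
    """Random-population scan of the five adjustable parameters.

    Each sample draws one factor per adjustable parameter from
    ``alpha_range`` (log-uniform by default, linear-uniform optionally),
    simulates a single-stimulus AP and classifies the EAD mechanism.
    Fractions are reported among the EAD-positive samples; identical
    seeds give identical results.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = alpha_range
    if lo <= 0 or hi < lo:
        raise ValueError("invalid alpha range")
    if distribution not in ("log_uniform", "uniform"):
        raise ValueError(f"unknown distribution {distribution!r}")
    rng = np.random.default_rng(seed)
    if base is None:
        base = control_parameters(fss_flattened=flattened)
    if protocol is None:
        protocol = build_stimulus("single")
    y0 = variant_initial_state(base)

    draws = rng.random((n, len(ALPHA_NAMES)))
    if distribution == "log_uniform":
        factors = np.exp(np.log(lo) + draws * (np.log(hi) - np.log(lo)))
    else:
        factors = lo + draws * (hi - lo)

    rows = []
    n_div = 0
    for k in range(n):
        alpha = {name: float(factors[k, i]) for i, name in enumerate(ALPHA_NAMES)}
        params = apply_scaling(base, alpha)
        try:
            c = run_dissection(params, protocol, t_end=t_end, dt=dt, y0=y0,
                               with_confirmatory=False)
            label = c.label
        except SimulationDiverged:
            label = "diverged"
            n_div += 1
        rows.append({**{f"alpha_{nm}": alpha[nm] for nm in ALPHA_NAMES},
                     "label": label})
    samples = pd.DataFrame(rows)
    ead_labels = ("typeI", "typeII", "typeIII", "typeIV")
    mask = samples["label"].isin(ead_labels)
    n_pos = int(mask.sum())
    fractions = {}
    for lab in ead_labels:
        fractions[lab] = (float((samples["label"] == lab).sum()) / n_pos
                          if n_pos else 0.0)
    return MonteCarloResult(
        seed=seed, n_samples=n, alpha_range=(lo, hi),
        distribution=distribution, flattened=flattened, samples=samples,
        n_ead_positive=n_pos, n_diverged=n_div, fractions=fractions)
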