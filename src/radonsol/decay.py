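"""Radon progeny decay chain and the activity-based solubility pipeline.

The experimental arm of the study: a liquid sample is exposed to radon-laden
air, sealed, and left for ~4 h until the short-lived progeny 214Pb and 214Bi
reach transient equilibrium with the dissolved 222Rn.  Their gamma activities,
measured repeatedly over up to 14 days, then decay with the 222Rn half-life;
back-extrapolating to the sealing time gives the initial activity, and
normalizing by the ambient radon activity concentration gives the
concentration-specific solubility S = C / D_Rn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from importlib import resources

#: default half-lives, hours: 222Rn (published value 3.8 d -> 3.8235 d
#: nuclide-chart precision), then nuclide-chart values for the progeny.
DEFAULT_HALF_LIVES_H = {
    "Rn222": 3.8235 * 24.0,
    "Po218": 3.098 / 60.0,
    "Pb214": 26.8 / 60.0,
    "Bi214": 19.9 / 60.0,
}

#: gamma lines used for activity determination, keV
GAMMA_LINES_KEV = {"Pb214": (242.0, 295.0, 352.0), "Bi214": (609.0,)}


@dataclass(frozen=True)
class NuclideChain:
    """Ordered linear decay chain with decay constants in 1/h.

    The minor 218Po -> 218At branch is ignored; the chain is strictly linear.
    An optional terminal stable member (lambda = 0) can be appended to make
    atom-number conservation explicit.
    """

    nuclides: tuple[str, ...] = ("Rn222", "Po218", "Pb214", "Bi214")
    half_lives_h: tuple[float, ...] = tuple(
        DEFAULT_HALF_LIVES_H[n] for n in ("Rn222", "Po218", "Pb214", "Bi214"))

    def __post_init__(self):
        if len(self.nuclides) != len(self.half_lives_h):
            raise ValueError("one half-life per nuclide required")
        if any(t <= 0 for t in self.half_lives_h):
            raise ValueError("half-lives must be > 0")

    @property
    def decay_constants(self) -> np.ndarray:
        """lambda_i = ln2 / t_half, 1/h."""
        return math.log(2.0) / np.asarray(self.half_lives_h)

    def index(self, nuclide: str) -> int:
        return self.nuclides.index(nuclide)

    def with_terminal_stable(self) -> "NuclideChain":
        """Chain extended by an absorbing stable end state (used for
        conservation checks); implemented as an extremely long half-life."""
        return NuclideChain(self.nuclides + ("stable",),
                            self.half_lives_h + (1e30,))

    def equilibrium_activity_ratio(self, nuclide: str) -> float:
        """Asymptotic A_nuclide / A_parent once transient equilibrium holds.

        From the Bateman solution, the slowest-decaying exponential
        (the parent's) dominates and the ratio tends to
        prod_{k=2..i} lambda_k / (lambda_k - lambda_1).
        """
        lam = self.decay_constants
        i = self.index(nuclide)
        ratio = 1.0
        for k in range(1, i + 1):
            ratio *= lam[k] / (lam[k] - lam[0])
        return ratio


@dataclass
class GammaSeries:
    """Timestamped activity measurements of one progeny nuclide."""

    times_h: np.ndarray
    activities_bq: np.ndarray
    sigmas_bq: np.ndarray | None = None
    nuclide: str = "Pb214"

    def __post_init__(self):
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.activities_bq = np.asarray(self.activities_bq, dtype=float)
        if self.sigmas_bq is not None:
            self.sigmas_bq = np.asarray(self.sigmas_bq, dtype=float)
        if len(self.times_h) != len(self.activities_bq):
            raise ValueError("times and activities must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("measurement times must be strictly increasing")

    def __len__(self):
        return len(self.times_h)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times_h,
            "activity_bq": self.activities_bq,
            "sigma_bq": (self.sigmas_bq if self.sigmas_bq is not None
                         else np.full(len(self), np.nan)),
            "nuclide": self.nuclide,
        })


@dataclass(frozen=True)
class ExperimentRecord:
    """One exposure run: progeny concentrations and ambient radon level."""

    liquid: str
    c_pb: float            # Bq/cm^3
    c_bi: float            # Bq/cm^3
    d_rn: float            # Bq/cm^3
    c_pb_err: float = 0.0
    c_bi_err: float = 0.0
    d_rn_err: float = 0.0
    sample_density: float = 1.0  # g/cm^3

    def __post_init__(self):
        if self.d_rn <= 0:
            raise ValueError("d_rn must be positive")
        if self.c_pb < 0 or self.c_bi < 0:
            raise ValueError("activity concentrations must be >= 0")


@dataclass
class SolubilityEstimate:
    """Per-run and aggregate concentration-specific solubility."""

    per_run: np.ndarray
    aggregate: float
    dispersion: float          # sample std over runs
    propagated_err: float      # quadrature-propagated measurement error
    liquid: str = ""

    def __post_init__(self):
        self.per_run = np.asarray(self.per_run, dtype=float)


# ---------------------------------------------------------------------------
# Bateman solution


def bateman_amounts(chain: NuclideChain, initial_amounts, t):
    """Atom numbers N_i(t) of a linear chain, closed-form Bateman solution.

    ``initial_amounts`` is one entry per chain member; ``t`` (hours) may be a
    scalar or array.  Near-degenerate decay constants are handled by an
    epsilon perturbation (1e-9 relative, documented behaviour) of the later
    constant, which keeps the distinct-rate formula well conditioned.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    lam = chain.decay_constants.copy()
    for i in range(len(lam)):
        for j in range(i):
            if abs(lam[i] - lam[j]) < 1e-12 * max(abs(lam[i]), 1e-300):
                lam[i] *= 1.0 + 1e-9
    n = len(lam)
    N0 = np.asarray(initial_amounts, dtype=float)
    out = np.zeros((n, len(t)))
    for m in range(n):          # source nuclide
        if N0[m] == 0.0:
            continue
        for i in range(m, n):   # descendant
            # product of branching rates lambda_m..lambda_{i-1}
            prefac = N0[m] * np.prod(lam[m:i])
            coeffs = np.zeros(i - m + 1)
            for j in range(m, i + 1):
                denom = 1.0
                for k in range(m, i + 1):
                    if k != j:
                        denom *= lam[k] - lam[j]
                coeffs[j - m] = 1.0 / denom
            out[i] += prefac * (coeffs[:, None] * np.exp(-np.outer(lam[m:i + 1], t))).sum(axis=0)
    # exact initial condition (avoids ~1e-12 cancellation residue at t = 0)
    at_zero = t == 0.0
    if np.any(at_zero):
        out[:, at_zero] = N0[:, None]
    return out


def bateman_activities(chain: NuclideChain, initial_amounts, t):
    """Activities A_i(t) = lambda_i N_i(t) (per hour units for N in atoms)."""
    N = bateman_amounts(chain, initial_amounts, t)
    return chain.decay_constants[:, None] * N


def equilibrium_time(chain: NuclideChain, tolerance: float = 1e-2,
                     daughters: tuple[str, ...] = ("Pb214", "Bi214"),
                     t_max_h: float = 48.0) -> float:
    """Earliest time (h) at which every daughter activity ratio is within
    ``tolerance`` (relative) of its asymptotic transient-equilibrium value,
    and stays there.
    """
    if not 0.0 < tolerance < 1.0:
        raise ValueError("tolerance must be in (0, 1)")
    n0 = np.zeros(len(chain.nuclides))
    n0[0] = 1.0
    t = np.linspace(1e-6, t_max_h, 20001)
    A = bateman_activities(chain, n0, t)
    ok = np.ones(len(t), dtype=bool)
    for d in daughters:
        i = chain.index(d)
        target = chain.equilibrium_activity_ratio(d)
        ok &= np.abs(A[i] / A[0] - target) <= tolerance * target
    # earliest time from which the condition holds for good
    idx = len(t)
    for k in range(len(t) - 1, -1, -1):
        if not ok[k]:
            break
        idx = k
    return 0.0 if idx == 0 else (float(t[idx]) if idx < len(t) else float("inf"))


# ---------------------------------------------------------------------------
# activity back-extrapolation and solubility


def fit_initial_activity(series: GammaSeries, chain: NuclideChain | None = None):
    """Back-extrapolate a progeny activity series to the sealing time t = 0.

    Past transient equilibrium the progeny decay is governed by the parent:
    A(t) = A0 exp(-lambda_Rn t) with lambda_Rn fixed, so A0 is the single
    linear parameter of a weighted least-squares fit.  Returns ``(A0, se)``;
    with per-point sigmas the weights are 1/sigma^2 and the standard error is
    the exact Gaussian one, otherwise weights are uniform and the error is
    scaled by the residual variance.
    """
    chain = chain or NuclideChain()
    if len(series) < 2:
        raise ValueError("need at least 2 measurements")
    if not np.any(series.activities_bq != 0):
        raise ValueError("all activities are zero")
    lam = chain.decay_constants[0]
    g = np.exp(-lam * series.times_h)
    y = series.activities_bq
    if series.sigmas_bq is not None and np.all(series.sigmas_bq > 0):
        w = 1.0 / series.sigmas_bq**2
        a0 = float(np.sum(w * y * g) / np.sum(w * g * g))
        se = float(1.0 / math.sqrt(np.sum(w * g * g)))
    else:
        a0 = float(np.sum(y * g) / np.sum(g * g))
        dof = max(len(series) - 1, 1)
        s2 = float(np.sum((y - a0 * g) ** 2) / dof)
        se = float(math.sqrt(s2 / np.sum(g * g)))
    return a0, se


def experimental_solubility(records) -> SolubilityEstimate:
    """Concentration-specific solubility from a set of exposure runs.

    Per run, S = mean(C_Pb, C_Bi) / D_Rn; the aggregate is the mean over
    runs.  The dispersion is the sample standard deviation over the
    individual per-gamma-line values (C_Pb/D_Rn and C_Bi/D_Rn separately),
    i.e. every measured line counts as one observation of S; the propagated
    error is the quadrature combination of the per-run measurement errors.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one record")
    s_runs, s_lines, var_runs = [], [], []
    for r in records:
        if r.d_rn <= 0:
            raise ValueError("d_rn must be positive")
        c = 0.5 * (r.c_pb + r.c_bi)
        s = c / r.d_rn
        s_runs.append(s)
        s_lines.extend([r.c_pb / r.d_rn, r.c_bi / r.d_rn])
        c_err = 0.5 * math.hypot(r.c_pb_err, r.c_bi_err)
        var_runs.append((c_err / r.d_rn) ** 2 + (s * r.d_rn_err / r.d_rn) ** 2)
    s_runs = np.array(s_runs)
    agg = float(np.mean(s_runs))
    disp = float(np.std(s_lines, ddof=1)) if len(s_lines) > 1 else 0.0
    prop = float(math.sqrt(sum(var_runs)) / len(s_runs))
    liquids = {r.liquid for r in records}
    return SolubilityEstimate(s_runs, agg, disp, prop,
                              liquid=liquids.pop() if len(liquids) == 1 else "mixed")


# ---------------------------------------------------------------------------
# bundled records


def load_experiment_records(path=None) -> list[ExperimentRecord]:
    """The bundled exposure-run records (see data/experiment_records.csv)."""
    if path is None:
        res = resources.files("radonsol.data") / "experiment_records.csv"
        with resources.as_file(res) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    return [
        ExperimentRecord(r.liquid, r.c_pb, r.c_bi, r.d_rn,
                         r.c_pb_err, r.c_bi_err, r.d_rn_err, r.sample_density)
        for r in df.itertuples()
    ]


def solubility_by_liquid(records=None) -> dict[str, SolubilityEstimate]:
    """Group records by liquid and estimate each liquid's solubility."""
    records = records if records is not None else load_experiment_records()
    out = {}
    for liquid in dict.fromkeys(r.liquid for r in records):
        out[liquid] = experimental_solubility([r for r in records if r.liquid == liquid])
    return out


def read_gamma_series_csv(path) -> list[GammaSeries]:
    """Read gamma series from CSV (time_h, activity_bq, sigma_bq, nuclide),
    one series per nuclide label; malformed rows raise with line numbers."""
    df = pd.read_csv(path, comment="#")
    required = {"time_h", "activity_bq"}
    if not required.issubset(df.columns):
        raise ValueError(f"missing columns: {sorted(required - set(df.columns))}")
    bad = df.index[df[["time_h", "activity_bq"]].isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"malformed rows at lines {[int(i) + 2 for i in bad]}")
    if "nuclide" not in df.columns:
        df["nuclide"] = "Pb214"
    out = []
    for nuc, sub in df.groupby("nuclide", sort=False):
        sub = sub.sort_values("time_h")
        sig = sub["sigma_bq"].to_numpy() if "sigma_bq" in sub else None
        if sig is not None and np.any(np.isnan(sig)):
            sig = None
        out.append(GammaSeries(sub["time_h"].to_numpy(),
                               sub["activity_bq"].to_numpy(), sig, nuc))
    return out
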