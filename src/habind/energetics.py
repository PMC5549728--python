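"""Umbrella-sampling post-processing: WHAM, well depths, populations.

Umbrella sampling restrains the reaction coordinate xi (here the distance
between the ligand and the binding-site pull group) in a ladder of harmonic
windows; the weighted-histogram analysis method (WHAM) recombines the
biased histograms into the unbiased potential of mean force G(xi).  The
self-consistent equations iterated here are the standard ones,

    p_i  =  sum_k n_ki  /  sum_k N_k exp((f_k - U_k(xi_i)) / kBT)
    exp(-f_k / kBT)  =  sum_i p_i exp(-U_k(xi_i) / kBT)

with p_i the unbiased bin probability, U_k the bias of window k and f_k its
free energy.  Profiles are anchored so the mean of G over a bulk region
(by default the last 20 % of the grid) is zero; bin uncertainties come from
a Bayesian bootstrap over samples.

Two thermal constants are supported and always reported alongside
converted numbers: a rounded "paper-arithmetic" kBT of 2.5 kJ/mol, which
reproduces printed conversions such as 22 / 2.5 = 8.8, and the physical
R*T at the configured temperature (~2.577 kJ/mol at 310 K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import ConvergenceError, CoverageError, DataError, GridRangeError

GAS_CONSTANT_KJ = 8.31446261815324e-3  # kJ mol^-1 K^-1


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and the thermal constant used for conversions."""

    temperature: float = 310.0          # K
    convention: str = "paper-arithmetic"  # or "physical"

    @property
    def kbt(self) -> float:
        """Thermal constant kBT in kJ/mol under the chosen convention."""
        if self.convention == "paper-arithmetic":
            return 2.5
        if self.convention == "physical":
            return GAS_CONSTANT_KJ * self.temperature
        raise DataError(f"unknown thermal convention {self.convention!r}")


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic restraint plus sampled xi series."""

    center: float                 # nm
    spring_k: float               # kJ mol^-1 nm^-2; 0 = unbiased window
    samples: np.ndarray           # nm
    temperature: float = 310.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.samples.size < 1:
            raise DataError("umbrella window needs at least one sample")
        if self.spring_k < 0:
            raise DataError("spring constant must be >= 0")

    def bias(self, xi: np.ndarray) -> np.ndarray:
        """Bias potential U_k(xi) in kJ/mol."""
        return 0.5 * self.spring_k * (np.asarray(xi) - self.center) ** 2


@dataclass
class PMFProfile:
    """Free energy vs reaction coordinate, anchored at the bulk region."""

    xi: np.ndarray                # bin centers, nm, strictly increasing
    g: np.ndarray                 # kJ/mol
    sigma: np.ndarray             # kJ/mol, >= 0
    bulk_region: tuple[float, float]
    temperature: float = 310.0
    #: bootstrap profile replicates (n_boot, len(xi)); functionals of the
    #: profile (well depth, populations) get their uncertainty from these
    bootstrap_g: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.xi) <= 0):
            raise DataError("xi grid must be strictly increasing")
        if np.any(self.sigma < 0):
            raise DataError("uncertainties must be >= 0")

    def bulk_mask(self) -> np.ndarray:
        lo, hi = self.bulk_region
        return (self.xi >= lo) & (self.xi <= hi)

    def anchored(self) -> "PMFProfile":
        mask = self.bulk_mask()
        if not mask.any():
            raise GridRangeError("bulk anchor region lies outside the grid")
        return PMFProfile(xi=self.xi, g=self.g - self.g[mask].mean(),
                          sigma=self.sigma, bulk_region=self.bulk_region,
                          temperature=self.temperature,
                          bootstrap_g=self.bootstrap_g)

    def to_tsv(self, path) -> None:
        header = "xi_nm\tG_kJ_per_mol\tsigma_kJ_per_mol"
        np.savetxt(path, np.column_stack([self.xi, self.g, self.sigma]),
                   delimiter="\t", header=header, comments="")


def _coverage_check(windows: Sequence[UmbrellaWindow]) -> None:
    """Windows must overlap pairwise along their ordered sampled ranges."""
    spans = sorted((w.samples.min(), w.samples.max()) for w in windows)
    for (lo1, hi1), (lo2, hi2) in zip(spans, spans[1:]):
        if lo2 > hi1:
            raise CoverageError(
                f"umbrella windows leave a gap on ({hi1:.4f}, {lo2:.4f}) nm")


def _wham_solve(log_hist: np.ndarray, u_red: np.ndarray,
                log_n_k: np.ndarray, tol: float, max_iter: int,
                g0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Self-consistent WHAM in log space.

    log_hist : (bins,) log of total counts per bin (may be -inf)
    u_red    : (windows, bins) reduced bias U_k(xi_i)/kBT
    log_n_k  : (windows,) log sample counts
    Returns (log_p normalized, g_k reduced window free energies).
    """
    n_win = u_red.shape[0]
    g = np.zeros(n_win) if g0 is None else g0.copy()
    for _ in range(max_iter):
        # log denominators per bin
        log_den = logsumexp(log_n_k[:, None] + g[:, None] - u_red, axis=0)
        log_p = log_hist - log_den
        log_p -= logsumexp(log_p[np.isfinite(log_p)])
        g_new = -logsumexp(log_p[None, :] - u_red, axis=1,
                           b=np.isfinite(log_p)[None, :].astype(float))
        g_new -= g_new[0]
        delta = np.max(np.abs(g_new - g))
        g = g_new
        if delta < tol:
            return log_p, g
    raise ConvergenceError(
        f"WHAM did not converge in {max_iter} iterations (residual {delta:.3g})")


def wham(windows: Sequence[UmbrellaWindow], bins: int = 100,
         tol: float = 1e-6, max_iter: int = 100_000,
         thermo: ThermoParams = ThermoParams(),
         bulk_fraction: float = 0.2,
         n_bootstrap: int = 50, seed: int | None = 0,
         grid: np.ndarray | None = None,
         min_count: int = 5) -> PMFProfile:
    """Estimate the PMF from umbrella windows by self-consistent WHAM.

    Parameters
    ----------
    bins : int
        Histogram bins over the union of sampled ranges (ignored when an
        explicit ``grid`` of bin edges is passed).
    bulk_fraction : float
        The trailing fraction of the grid used as the zero-anchor region.
    n_bootstrap : int
        Bayesian-bootstrap resamples for per-bin uncertainties (0 disables).
    min_count : int
        Bins with fewer total counts are dropped from the profile (edge
        bins with a handful of samples carry kBT-scale noise).
    """
    if len(windows) == 0:
        raise DataError("need at least one umbrella window")
    _coverage_check(windows)
    kbt = thermo.kbt
    all_samples = np.concatenate([w.samples for w in windows])
    if grid is None:
        lo, hi = all_samples.min(), all_samples.max()
        edges = np.linspace(lo, hi + 1e-12, bins + 1)
    else:
        edges = np.asarray(grid, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])

    u_red = np.array([w.bias(centers) / kbt for w in windows])
    n_k = np.array([w.samples.size for w in windows], dtype=float)
    log_n_k = np.log(n_k)

    def profile_from_hist(hist: np.ndarray, g0=None):
        with np.errstate(divide="ignore"):
            log_hist = np.log(hist)
        log_p, g = _wham_solve(log_hist, u_red, log_n_k, tol, max_iter, g0)
        return -kbt * log_p, g

    hist = np.sum([np.histogram(w.samples, bins=edges)[0] for w in windows],
                  axis=0).astype(float)
    g_vals, g_win = profile_from_hist(hist)

    sigma = np.zeros_like(g_vals)
    boots: list[np.ndarray] = []
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_bootstrap):
            bh = np.zeros(len(centers))
            for w in windows:
                wts = rng.dirichlet(np.ones(w.samples.size)) * w.samples.size
                bh += np.histogram(w.samples, bins=edges, weights=wts)[0]
            try:
                bg, _ = profile_from_hist(bh, g0=g_win)
            except ConvergenceError:
                continue
            boots.append(bg - np.nanmean(bg[np.isfinite(bg)]))
        if boots:
            arr = np.array(boots)
            with np.errstate(invalid="ignore"):
                sigma = np.nanstd(arr, axis=0)
            sigma = np.where(np.isfinite(sigma), sigma, 0.0)

    finite = np.isfinite(g_vals) & (hist >= min_count)
    xi = centers[finite]
    g_f = g_vals[finite]
    s_f = sigma[finite]
    bulk_lo = xi[-1] - bulk_fraction * (xi[-1] - xi[0])
    boot_g = np.array(boots)[:, finite] if boots else None
    prof = PMFProfile(xi=xi, g=g_f, sigma=s_f,
                      bulk_region=(bulk_lo, xi[-1]),
                      temperature=thermo.temperature,
                      bootstrap_g=boot_g)
    return prof.anchored()


def delta_g_min(pmf: PMFProfile) -> float:
    """Well depth: min G minus the mean G over the bulk anchor region."""
    mask = pmf.bulk_mask()
    if not mask.any():
        raise GridRangeError("bulk anchor region lies outside the grid")
    return float(pmf.g.min() - pmf.g[mask].mean())


def delta_g_min_uncertainty(pmf: PMFProfile) -> float:
    """Bootstrap standard error of the well depth.

    Evaluates the depth functional on every bootstrap profile replicate;
    NaN when the profile carries no replicates.
    """
    if pmf.bootstrap_g is None or len(pmf.bootstrap_g) < 2:
        return float("nan")
    mask = pmf.bulk_mask()
    finite_rows = np.all(np.isfinite(pmf.bootstrap_g), axis=1)
    reps = pmf.bootstrap_g[finite_rows]
    depths = reps.min(axis=1) - reps[:, mask].mean(axis=1)
    return float(depths.std(ddof=1))


def default_partition(pmf: PMFProfile, thermo: ThermoParams = ThermoParams()
                      ) -> float:
    """Bound/unbound partition point xi*.

    First grid point past the minimum where G has risen to within 1 kBT of
    the bulk level (zero after anchoring).
    """
    anchored = pmf.anchored()
    imin = int(np.argmin(anchored.g))
    after = np.nonzero(anchored.g[imin:] >= -thermo.kbt)[0]
    if after.size == 0 or imin + after[0] >= len(anchored.xi) - 1:
        raise GridRangeError("no partition point inside the grid")
    return float(anchored.xi[imin + after[0]])


def delta_g_population(pmf: PMFProfile, partition: float | None = None,
                       thermo: ThermoParams = ThermoParams()) -> float:
    """Population-integrated binding free energy.

    -kBT ln( integral_{xi < xi*} exp(-G/kBT) dxi
             / integral_{xi >= xi*} exp(-G/kBT) dxi ),
    trapezoidal on the grid.  Unlike the point-minimum depth this accounts
    for the width of the bound basin, so a wide shallow well can be more
    populated than its depth alone suggests.
    """
    if partition is None:
        partition = default_partition(pmf, thermo)
    xi, g = pmf.xi, pmf.g
    if not (xi[0] < partition < xi[-1]):
        raise GridRangeError(f"partition {partition} outside grid")
    w = np.exp(-g / thermo.kbt)
    bound = (xi < partition)
    if bound.sum() < 2 or (~bound).sum() < 2:
        raise GridRangeError("degenerate integral on one side of the partition")
    num = np.trapezoid(w[bound], xi[bound])
    den = np.trapezoid(w[~bound], xi[~bound])
    if num <= 0 or den <= 0:
        raise GridRangeError("zero-measure population integral")
    return float(-thermo.kbt * math.log(num / den))


def to_kbt(value_kj: float, thermo: ThermoParams = ThermoParams()) -> float:
    """Convert a kJ/mol free energy to thermal units (kBT)."""
    return value_kj / thermo.kbt


def preference_factor(dg_a: float, dg_b: float,
                      thermo: ThermoParams = ThermoParams()) -> float:
    """Boltzmann preference of state a over state b.

    exp((dG_b - dG_a)/kBT): > 1 when a binds more strongly (more negative
    dG).  preference_factor(x, x) = 1 and
    preference_factor(a, b) * preference_factor(b, a) = 1.
    """
    if not (math.isfinite(dg_a) and math.isfinite(dg_b)):
        raise DataError("free energies must be finite")
    return math.exp((dg_b - dg_a) / thermo.kbt)


@dataclass
class BindingEnergetics:
    """Summary energetics of one PMF (optionally compared with a second)."""

    dg_min_kj: float
    dg_min_kbt: float
    dg_pop_kj: float | None
    kbt_kj: float
    convention: str
    preference_vs_other: float | None = None

    @classmethod
    def from_profile(cls, pmf: PMFProfile, other: PMFProfile | None = None,
                     thermo: ThermoParams = ThermoParams()
                     ) -> "BindingEnergetics":
        dgm = delta_g_min(pmf)
        try:
            dgp = delta_g_population(pmf, thermo=thermo)
        except GridRangeError:
            dgp = None
        pref = None
        if other is not None:
            pref = preference_factor(dgm, delta_g_min(other), thermo)
        return cls(dg_min_kj=dgm, dg_min_kbt=to_kbt(dgm, thermo),
                   dg_pop_kj=dgp, kbt_kj=thermo.kbt,
                   convention=thermo.convention, preference_vs_other=pref)


# --------------------------------------------------------------------------
# window-file IO (de facto umbrella time-series layout)
# --------------------------------------------------------------------------

def read_window_file(path: str | Path,
                     temperature: float = 310.0) -> UmbrellaWindow:
    """Read one umbrella window from a plain-text time-series file.

    Header comment lines declare ``center`` (nm) and ``spring_k``
    (kJ mol^-1 nm^-2); the body holds ``time xi`` pairs.
    """
    center = spring = None
    times, xis = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("center"):
                    center = float(body.split()[-1])
                elif body.startswith("spring_k"):
                    spring = float(body.split()[-1])
                continue
            t, x = line.split()[:2]
            times.append(float(t))
            xis.append(float(x))
    if center is None or spring is None:
        raise DataError(f"{path}: missing '# center' or '# spring_k' header")
    return UmbrellaWindow(center=center, spring_k=spring,
                          samples=np.asarray(xis), temperature=temperature)


def write_window_file(window: UmbrellaWindow, path: str | Path,
                      dt: float = 1.0) -> None:
    with open(path, "w") as fh:
        fh.write(f"# center {window.center:.6f}\n")
        fh.write(f"# spring_k {window.spring_k:.6f}\n")
        fh.write("# time_ps xi_nm\n")
        for i, x in enumerate(window.samples):
            fh.write(f"{i * dt:.3f} {x:.8f}\n")
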