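"""Nitroxide spin-probe spectral statistics.

Two scalar reporters of membrane fluidity are computed from first-derivative
EPR spectra:

* the rotational correlation time of a probe tumbling in the bilayer,

      tau = 5.95 * dH0 * (sqrt(I0/I+1) + sqrt(I0/I-1) - 2) * 1e-10  s,

  with ``dH0`` the peak-to-peak width of the central line (in gauss by
  convention here; the unit is an explicit argument) and ``I0``, ``I+1``,
  ``I-1`` the peak-to-peak amplitudes of the nitroxide triplet lines
  (m_I = 0, +1 low field, -1 high field);

* the partition parameter of an amphiphilic probe distributed between the
  lipid (H line) and aqueous (P line) components of a split high-field
  line,

      F = H / (H + P),  in [0, 1].

A synthetic spectrum generator (first-derivative Lorentzian or Gaussian
lines) and a peak-to-trough measurement routine make both formulas testable
end-to-end without instrument data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .constants import GAUSS_TO_MT

__all__ = ["EPRSpectrum", "TripletParameters", "PartitionLines",
           "ProbeParameters", "rotational_correlation_time",
           "partition_coefficient", "normalize_series", "synthesize_triplet",
           "synthesize_split_highfield", "measure_spectrum",
           "measure_partition", "MeasurementError", "read_spectrum",
           "write_spectrum"]


class MeasurementError(ValueError):
    """A spectral line expected by the measurement could not be resolved."""


@dataclass
class TripletParameters:
    """Peak-to-peak amplitudes and central-line width of a nitroxide
    triplet.  Amplitudes are in arbitrary units; ``delta_h0`` in gauss;
    ``a_n`` is the hyperfine splitting used by the generator, in mT."""

    I0: float
    I_plus1: float
    I_minus1: float
    delta_h0: float
    a_n: float = 1.5

    def __post_init__(self):
        if min(self.I0, self.I_plus1, self.I_minus1) <= 0:
            raise ValueError("line amplitudes must be positive")
        if self.delta_h0 <= 0:
            raise ValueError("delta_h0 must be positive")


@dataclass
class PartitionLines:
    """Amplitudes of the two high-field components: H (lipid phase) and
    P (aqueous phase)."""

    H: float
    P: float

    def __post_init__(self):
        if self.H < 0 or self.P < 0 or self.H + self.P <= 0:
            raise ValueError("need H >= 0, P >= 0, H + P > 0")


@dataclass
class ProbeParameters:
    """Derived scalar statistics for one sample."""

    tau: Optional[float] = None       # s
    F: Optional[float] = None         # dimensionless, [0, 1]


@dataclass
class EPRSpectrum:
    """First-derivative spectrum on a uniform magnetic-field axis (mT)."""

    field_mT: np.ndarray
    amplitude: np.ndarray
    probe_kind: str = "triplet"        # "triplet" | "triplet_split_highfield"
    generation: Optional[dict] = None  # generator parameters when synthetic

    def __post_init__(self):
        self.field_mT = np.asarray(self.field_mT, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.field_mT.ndim != 1 or self.field_mT.shape != self.amplitude.shape:
            raise ValueError("field and amplitude must be matching 1-d arrays")
        steps = np.diff(self.field_mT)
        if len(steps) and (steps.min() <= 0 or
                           not np.allclose(steps, steps[0], rtol=1e-6)):
            raise ValueError("field axis must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude must be finite everywhere")

    @property
    def step(self) -> float:
        return float(self.field_mT[1] - self.field_mT[0])


def rotational_correlation_time(tp: TripletParameters,
                                delta_h0_unit: str = "gauss") -> float:
    """tau = 5.95 * dH0 * (sqrt(I0/I+1) + sqrt(I0/I-1) - 2) * 1e-10 s.

    ``delta_h0_unit`` states the unit ``tp.delta_h0`` is expressed in
    ("gauss" is the conventional choice for this formula; "mT" converts).
    Invariant under a common rescaling of the three amplitudes.
    """
    if delta_h0_unit == "gauss":
        dh = tp.delta_h0
    elif delta_h0_unit == "mT":
        dh = tp.delta_h0 / GAUSS_TO_MT
    else:
        raise ValueError(f"unknown unit {delta_h0_unit!r}")
    return 5.95 * dh * (math.sqrt(tp.I0 / tp.I_plus1)
                        + math.sqrt(tp.I0 / tp.I_minus1) - 2.0) * 1e-10


def partition_coefficient(pl: PartitionLines) -> float:
    """F = H/(H + P), the lipid-phase fraction of the split high-field line."""
    return pl.H / (pl.H + pl.P)


def normalize_series(values: Sequence[float], baseline_index: int = 0) -> np.ndarray:
    """Divide a concentration series by its baseline element (tau/tau0,
    F/F0, Ep/Ep0 all use this pattern)."""
    v = np.asarray(values, dtype=float)
    base = v[baseline_index]
    if base == 0:
        raise ZeroDivisionError("baseline value is zero")
    return v / base


# --- synthetic spectra -------------------------------------------------

# peak-to-peak height of the unit-scale first-derivative shapes below
_LOR_PP = 9.0 / (8.0 * math.sqrt(3.0))          # max-min of -u/(1+u^2)^2
_GAU_PP = 2.0 * math.exp(-0.5)                  # max-min of -u*exp(-u^2/2)


def _deriv_line(x: np.ndarray, center: float, dh_pp_mT: float,
                amplitude_pp: float, shape: str) -> np.ndarray:
    """One first-derivative line with requested peak-to-peak width (mT)
    and peak-to-peak amplitude."""
    if shape == "lorentzian":
        gamma = math.sqrt(3.0) * dh_pp_mT / 2.0   # HWHM; extrema at +-g/sqrt3
        u = (x - center) / gamma
        return (amplitude_pp / _LOR_PP) * (-u / (1.0 + u * u) ** 2)
    if shape == "gaussian":
        s = dh_pp_mT / 2.0                        # extrema at +-s
        u = (x - center) / s
        return (amplitude_pp / _GAU_PP) * (-u * np.exp(-0.5 * u * u))
    raise ValueError(f"unknown line shape {shape!r}")


def synthesize_triplet(tp: TripletParameters,
                       grid: Optional[np.ndarray] = None,
                       line_shape: str = "lorentzian",
                       noise_sd: float = 0.0,
                       seed: Optional[int] = None) -> EPRSpectrum:
    """Three first-derivative lines at -a_n, 0, +a_n (m_I = +1, 0, -1) with
    peak-to-peak amplitudes I+1, I0, I-1 and common width delta_h0.

    Default grid: 4096 points spanning +-(a_n + 2 mT).  Gaussian noise of
    standard deviation ``noise_sd`` (same units as the amplitudes) is added
    reproducibly from ``seed``.
    """
    if grid is None:
        half = tp.a_n + 2.0
        grid = np.linspace(-half, half, 4096)
    dh_mT = tp.delta_h0 * GAUSS_TO_MT
    y = (_deriv_line(grid, -tp.a_n, dh_mT, tp.I_plus1, line_shape)
         + _deriv_line(grid, 0.0, dh_mT, tp.I0, line_shape)
         + _deriv_line(grid, +tp.a_n, dh_mT, tp.I_minus1, line_shape))
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(grid))
    return EPRSpectrum(grid, y, probe_kind="triplet",
                       generation={"I0": tp.I0, "I_plus1": tp.I_plus1,
                                   "I_minus1": tp.I_minus1,
                                   "delta_h0_G": tp.delta_h0, "a_n": tp.a_n,
                                   "line_shape": line_shape,
                                   "noise_sd": noise_sd, "seed": seed})


def synthesize_split_highfield(tp: TripletParameters, split: float = 0.5,
                               H_frac: float = 0.5,
                               grid: Optional[np.ndarray] = None,
                               line_shape: str = "lorentzian",
                               noise_sd: float = 0.0,
                               seed: Optional[int] = None) -> EPRSpectrum:
    """Triplet whose high-field line is split into a lipid-phase component
    H (at +a_n) and an aqueous-phase component P (at +a_n + split, in mT),
    with amplitudes H_frac and 1 - H_frac of I-1."""
    if not 0.0 <= H_frac <= 1.0:
        raise ValueError("H_frac must be in [0, 1]")
    if grid is None:
        half = tp.a_n + split + 2.0
        grid = np.linspace(-half, half, 8192)
    dh_mT = tp.delta_h0 * GAUSS_TO_MT
    y = (_deriv_line(grid, -tp.a_n, dh_mT, tp.I_plus1, line_shape)
         + _deriv_line(grid, 0.0, dh_mT, tp.I0, line_shape))
    if H_frac > 0:
        y = y + _deriv_line(grid, tp.a_n, dh_mT, H_frac * tp.I_minus1,
                            line_shape)
    if H_frac < 1:
        y = y + _deriv_line(grid, tp.a_n + split, dh_mT,
                            (1.0 - H_frac) * tp.I_minus1, line_shape)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(grid))
    return EPRSpectrum(grid, y, probe_kind="triplet_split_highfield",
                       generation={"I0": tp.I0, "I_plus1": tp.I_plus1,
                                   "I_minus1": tp.I_minus1,
                                   "delta_h0_G": tp.delta_h0, "a_n": tp.a_n,
                                   "split": split, "H_frac": H_frac,
                                   "line_shape": line_shape,
                                   "noise_sd": noise_sd, "seed": seed})


# --- measurement -------------------------------------------------------

def _refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Parabolic sub-grid refinement of an extremum at index i."""
    if i <= 0 or i >= len(x) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y[i])
    d = 0.5 * (y0 - y2) / denom
    d = max(-0.5, min(0.5, d))
    step = x[1] - x[0]
    return float(x[i] + d * step), float(y1 - 0.25 * (y0 - y2) * d)


def _line_pp(sp: EPRSpectrum, center: float, window: float
             ) -> tuple[float, float, float, float]:
    """Peak-to-trough measurement of one first-derivative line inside
    ``center +- window``; returns (amplitude, width_mT, x_max, x_min)."""
    m = (sp.field_mT >= center - window) & (sp.field_mT <= center + window)
    if m.sum() < 5:
        raise MeasurementError(f"no data around {center:.2f} mT")
    x = sp.field_mT[m]
    y = sp.amplitude[m]
    i_hi = int(np.argmax(y))
    i_lo = int(np.argmin(y))
    x_hi, y_hi = _refine(x, y, i_hi)
    x_lo, y_lo = _refine(x, y, i_lo)
    amp = y_hi - y_lo
    if amp <= 0 or not (x_hi < x_lo):
        raise MeasurementError(
            f"line near {center:.2f} mT not resolved as a first-derivative "
            "peak-trough pair")
    return amp, x_lo - x_hi, x_hi, x_lo


def _guess_centers(sp: EPRSpectrum) -> tuple[float, float]:
    """(a_n, dh_pp) estimated from the three largest peak-trough pairs of an
    unannotated triplet."""
    y = sp.amplitude
    scale = float(np.max(np.abs(y)))
    if scale == 0:
        raise MeasurementError("flat spectrum: no lines at all")
    peaks, _ = find_peaks(y, prominence=0.05 * scale)
    troughs, _ = find_peaks(-y, prominence=0.05 * scale)
    if len(peaks) < 3 or len(troughs) < 3:
        raise MeasurementError(
            f"expected 3 lines, resolved {min(len(peaks), len(troughs))}")
    # each line is a peak followed by the nearest trough to its right
    pairs = []
    for p in peaks:
        t = troughs[troughs > p]
        if len(t):
            pairs.append((y[p] - y[t[0]], p, t[0]))
    pairs.sort(reverse=True)
    best = sorted(pairs[:3], key=lambda z: z[1])
    centers = [0.5 * (sp.field_mT[p] + sp.field_mT[t]) for _, p, t in best]
    a_n = 0.5 * (centers[2] - centers[0])
    _, p, t = best[1]
    dh = sp.field_mT[t] - sp.field_mT[p]
    return a_n, dh


def _fit_lines(x: np.ndarray, y: np.ndarray, p0: list[tuple[float, float, float]],
               shape: str, center_slack: float) -> list[tuple[float, float, float]]:
    """Joint least-squares fit of K first-derivative lines.

    ``p0`` holds (amplitude_pp, center, dh_pp) triples; returns refined
    triples (falls back to ``p0`` if the fit fails to converge).
    """
    from scipy.optimize import curve_fit

    k = len(p0)

    def model(xx, *theta):
        out = np.zeros_like(xx)
        for i in range(k):
            amp, cen, dh = theta[3 * i: 3 * i + 3]
            out = out + _deriv_line(xx, cen, dh, amp, shape)
        return out

    theta0 = []
    lo = []
    hi = []
    for amp, cen, dh in p0:
        theta0 += [max(amp, 1e-12), cen, dh]
        lo += [0.0, cen - center_slack, dh / 5.0]
        hi += [np.inf, cen + center_slack, dh * 5.0]
    try:
        theta, _ = curve_fit(model, x, y, p0=theta0, bounds=(lo, hi),
                             maxfev=5000)
    except Exception:
        return p0
    return [tuple(theta[3 * i: 3 * i + 3]) for i in range(k)]


def measure_spectrum(sp: EPRSpectrum, refine: bool = True) -> TripletParameters:
    """Measure I0, I+1, I-1 and delta_h0 from a triplet spectrum.

    Lines are first located as peak-to-trough excursions in windows around
    the known centers (generator metadata) or around centers estimated from
    the three largest peak-trough pairs; by default the estimates are then
    refined by a joint least-squares fit of three first-derivative lines,
    which removes tail overlap between lines and averages grid noise.
    ``delta_h0`` is the field distance between the central line's extrema,
    converted to gauss.
    """
    if sp.generation is not None:
        a_n = sp.generation["a_n"]
        dh_guess = sp.generation["delta_h0_G"] * GAUSS_TO_MT
        shape = sp.generation.get("line_shape", "lorentzian")
    else:
        a_n, dh_guess = _guess_centers(sp)
        shape = "lorentzian"
    window = min(0.6 * a_n, max(1.2 * dh_guess, 10 * sp.step))
    I_p, dh_p, _, _ = _line_pp(sp, -a_n, window)
    I_0, dh_mT, _, _ = _line_pp(sp, 0.0, window)
    I_m, dh_m, _, _ = _line_pp(sp, +a_n, window)
    if refine:
        fitted = _fit_lines(sp.field_mT, sp.amplitude,
                            [(I_p, -a_n, dh_p), (I_0, 0.0, dh_mT),
                             (I_m, a_n, dh_m)],
                            shape, center_slack=max(3 * dh_guess, 0.2))
        (I_p, _, _), (I_0, _, dh_mT), (I_m, _, _) = fitted
    return TripletParameters(I0=I_0, I_plus1=I_p, I_minus1=I_m,
                             delta_h0=dh_mT / GAUSS_TO_MT, a_n=a_n)


def measure_partition(sp: EPRSpectrum, split: Optional[float] = None
                      ) -> PartitionLines:
    """Measure the H and P amplitudes of a split high-field line.

    The two components sit at the known high-field center and ``split`` mT
    above it (generator metadata used when available); each is measured as
    its own peak-to-trough excursion with nearest-extremum assignment.
    """
    if sp.generation is not None:
        a_n = sp.generation["a_n"]
        split = sp.generation.get("split", split)
        dh_guess = sp.generation["delta_h0_G"] * GAUSS_TO_MT
        shape = sp.generation.get("line_shape", "lorentzian")
    else:
        a_n, dh_guess = _guess_centers(sp)
        shape = "lorentzian"
    if split is None:
        raise MeasurementError("the H-P splitting must be known or supplied")
    window = min(0.45 * split, max(2.0 * dh_guess, 10 * sp.step))
    try:
        H, dh_h, _, _ = _line_pp(sp, a_n, window)
    except MeasurementError:
        H, dh_h = 0.0, dh_guess
    try:
        P, dh_p, _, _ = _line_pp(sp, a_n + split, window)
    except MeasurementError:
        P, dh_p = 0.0, dh_guess
    if H + P <= 0:
        raise MeasurementError("neither high-field component (H, P) resolved")
    # joint fit of the two components over the high-field region removes
    # their mutual tail overlap
    m = ((sp.field_mT >= a_n - max(2 * dh_guess, 0.3)) &
         (sp.field_mT <= a_n + split + max(2 * dh_guess, 0.3)))
    fitted = _fit_lines(sp.field_mT[m], sp.amplitude[m],
                        [(H, a_n, dh_h), (P, a_n + split, dh_p)],
                        shape, center_slack=0.4 * split)
    H = max(0.0, fitted[0][0])
    P = max(0.0, fitted[1][0])
    if H + P <= 0:
        raise MeasurementError("neither high-field component (H, P) resolved")
    return PartitionLines(H=H, P=P)


# --- spectrum file I/O -------------------------------------------------

def write_spectrum(sp: EPRSpectrum, path) -> None:
    """Two-column delimited text: field_mT, amplitude.  Generator metadata
    is stored in '# key=value' header comments so a written synthetic
    spectrum round-trips losslessly through :func:`read_spectrum`."""
    import io as _io
    from pathlib import Path as _Path

    buf = _io.StringIO()
    buf.write(f"# probe_kind={sp.probe_kind}\n")
    if sp.generation is not None:
        for k, v in sp.generation.items():
            buf.write(f"# gen.{k}={v}\n")
    for x, y in zip(sp.field_mT, sp.amplitude):
        buf.write(f"{x:.9g}\t{y:.9g}\n")
    _Path(path).write_text(buf.getvalue())


def read_spectrum(path) -> EPRSpectrum:
    """Read a two-column delimited spectrum (mT, amplitude); '#' comments
    carrying 'gen.*' keys are restored as generator metadata."""
    from pathlib import Path as _Path

    kind = "triplet"
    gen: dict = {}
    xs, ys = [], []
    for line in _Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                k = k.strip()
                v = v.strip()
                if k == "probe_kind":
                    kind = v
                elif k.startswith("gen."):
                    if v == "None":
                        val = None
                    else:
                        try:
                            val = int(v)
                        except ValueError:
                            try:
                                val = float(v)
                            except ValueError:
                                val = v
                    gen[k[4:]] = val
            continue
        parts = line.replace(",", " ").split()
        xs.append(float(parts[0]))
        ys.append(float(parts[1]))
    return EPRSpectrum(np.asarray(xs), np.asarray(ys), probe_kind=kind,
                       generation=gen or None)
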