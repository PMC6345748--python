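"""Analytic potential and field of point currents in a concentric multilayer sphere.

Legendre-series solution for a point current source inside a piecewise
homogeneous sphere with an insulating outer boundary.  Used as the
independent oracle for the FEM solver and the field-extraction chain.

Model: layers numbered from the outside in, layer ``l`` occupying
``R_{l+1} < r <= R_l`` (the innermost layer fills the core).  Within each
layer the potential of a single axial source at radius ``b`` is

    phi_l(r, theta) = sum_n [ a_ln (r/R_l)^n + b_ln (R_inner_l/r)^(n+1) ] P_n(cos theta)
                      + [l == source layer] * phi_singular

with the free-medium singular part ``I/(4 pi sigma_s) * r_<^n / r_>^(n+1)``
summed over n.  Coefficients are matched by continuity of ``phi`` and of the
radial current density ``sigma dphi/dr`` at the interfaces, regularity at the
centre, and zero normal current at the outer boundary.  A single source is
given a uniform compensating outflow at the outer boundary (its n = 0
incompatibility); superposing a source/sink pair cancels the compensation
exactly and yields the insulated two-electrode solution.

Units: radii and positions in mm, conductivities in S/m, currents in mA;
potentials returned in V and fields in V/m (internally converted to SI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MM = 1e-3  # mm -> m
MA = 1e-3  # mA -> A


@dataclass(frozen=True)
class SphereLayerSpec:
    """Concentric layers plus point sources for the analytic solution."""

    radii_mm: tuple[float, ...] = (92.0, 85.0, 79.0, 75.0)
    conductivities: tuple[float, ...] = (0.08, 0.008, 1.8, 0.2)
    sources: tuple[tuple[tuple[float, float, float], float], ...] = field(
        default_factory=tuple
    )  # ((x, y, z) mm, current mA)
    n_terms: int = 200
    min_source_distance_mm: float = 1.0

    def __post_init__(self) -> None:
        r = np.asarray(self.radii_mm)
        if np.any(np.diff(r) >= 0):
            raise ValueError("radii must be strictly decreasing")
        if len(self.conductivities) != len(self.radii_mm):
            raise ValueError("one conductivity per layer required")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be > 0")
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")
        if self.sources:
            total = sum(c for _, c in self.sources)
            if abs(total) > 1e-12:
                raise ValueError("source currents must sum to zero")
            for pos, _ in self.sources:
                if np.linalg.norm(pos) >= self.radii_mm[0]:
                    raise ValueError("sources must lie strictly inside the sphere")


def _layer_of(spec: SphereLayerSpec, r: float) -> int:
    """Index of the layer containing radius r (0 = outermost)."""
    for l, R in enumerate(spec.radii_mm):
        inner = spec.radii_mm[l + 1] if l + 1 < len(spec.radii_mm) else 0.0
        if inner < r <= R or (l == len(spec.radii_mm) - 1 and r <= R):
            return l
    raise ValueError(f"radius {r} outside the sphere")


def _legendre_with_derivative(x: np.ndarray, n_max: int):
    """P_n(x) and P_n'(x) for n = 0..n_max by the three-term recurrence."""
    x = np.asarray(x, dtype=float)
    P = np.empty((n_max + 1,) + x.shape)
    dP = np.empty_like(P)
    P[0], dP[0] = 1.0, 0.0
    if n_max >= 1:
        P[1], dP[1] = x, 1.0
    for n in range(1, n_max):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
        dP[n + 1] = dP[n - 1] + (2 * n + 1) * P[n]
    return P, dP


def _solve_coefficients(spec: SphereLayerSpec, b: float, current_a: float):
    """Per-layer scaled series coefficients for one axial source.

    Returns arrays ``a[l, n]`` and ``bb[l, n]`` (SI units) for the scaled
    basis ``a (r/R_l)^n + bb (R_inner_l/r)^(n+1)``, n = 1..N; the n = 0 mode
    contributes only a gauge constant per layer outside the source layer and
    is resolved separately (closed form for a source in the outer layer).
    """
    R = np.asarray(spec.radii_mm, dtype=float) * MM
    sig = np.asarray(spec.conductivities, dtype=float)
    L = len(R)
    N = spec.n_terms
    b_m = b * MM
    s = _layer_of(spec, b)
    C = current_a / (4.0 * np.pi * sig[s])

    inner = np.concatenate([R[1:], [0.0]])  # inner radius per layer
    a = np.zeros((L, N + 1))
    bb = np.zeros((L, N + 1))

    for n in range(1, N + 1):
        # unknowns: a_0..a_{L-1}, bb_0..bb_{L-2}  (bb of core = 0)
        n_unk = 2 * L - 1
        A = np.zeros((n_unk, n_unk))
        rhs = np.zeros(n_unk)

        def ia(l):
            return l

        def ib(l):
            return L + l  # valid for l < L-1

        def basis(l, r):
            """(value, derivative) pairs of the two scaled basis fns at r."""
            va = (r / R[l]) ** n
            da = n * va / r
            if l < L - 1:
                vb = (inner[l] / r) ** (n + 1)
                db = -(n + 1) * vb / r
            else:
                vb = db = 0.0
            return va, da, vb, db

        def singular(l, r):
            """Free-medium source term and radial derivative at r in layer l."""
            if l != s:
                return 0.0, 0.0
            if r <= b_m:
                v = C * (r / b_m) ** n / b_m
                d = n * v / r
            else:
                v = C * (b_m / r) ** n / r
                d = -(n + 1) * v / r
            return v, d

        row = 0
        # outer boundary: zero normal current (n >= 1 modes)
        va, da, vb, db = basis(0, R[0])
        sv, sd = singular(0, R[0])
        A[row, ia(0)] = da
        if L > 1:
            A[row, ib(0)] = db
        rhs[row] = -sd
        row += 1
        # interface continuity
        for l in range(L - 1):
            r = R[l + 1]
            va_o, da_o, vb_o, db_o = basis(l, r)
            va_i, da_i, vb_i, db_i = basis(l + 1, r)
            sv_o, sd_o = singular(l, r)
            sv_i, sd_i = singular(l + 1, r)
            # potential continuity
            A[row, ia(l)] = va_o
            if l < L - 1:
                A[row, ib(l)] = vb_o
            A[row, ia(l + 1)] = -va_i
            if l + 1 < L - 1:
                A[row, ib(l + 1)] = -vb_i
            rhs[row] = sv_i - sv_o
            row += 1
            # current continuity
            A[row, ia(l)] = sig[l] * da_o
            if l < L - 1:
                A[row, ib(l)] = sig[l] * db_o
            A[row, ia(l + 1)] = -sig[l + 1] * da_i
            if l + 1 < L - 1:
                A[row, ib(l + 1)] = -sig[l + 1] * db_i
            rhs[row] = sig[l + 1] * sd_i - sig[l] * sd_o
            row += 1

        x = np.linalg.solve(A, rhs)
        a[:, n] = x[:L]
        bb[:-1, n] = x[L:]
    return a, bb, s, C, b_m, inner


def analytic_potential_and_field(
    spec: SphereLayerSpec, points_mm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Potential (V) and E field (V/m) at interior points by superposition.

    Raises if the series tail has not converged to a relative contribution
    below 1e-8 at any evaluation point.
    """
    if not spec.sources:
        raise ValueError("spec has no sources")
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    r_pts = np.linalg.norm(pts, axis=1)
    if np.any(r_pts >= spec.radii_mm[0]):
        raise ValueError("evaluation points must lie strictly inside the sphere")
    for pos, _ in spec.sources:
        d = np.linalg.norm(pts - np.asarray(pos), axis=1)
        if np.any(d < spec.min_source_distance_mm):
            raise ValueError("evaluation point too close to a source singularity")
    # the monopole (n = 0) mode is a pure gauge constant only below the
    # sources; restrict evaluation there so omitting it is exact
    min_b = min(np.linalg.norm(pos) for pos, _ in spec.sources)
    if np.any(r_pts >= min_b):
        raise ValueError(
            "evaluation points must lie below the smallest source radius "
            f"({min_b:.1f} mm)"
        )

    phi = np.zeros(len(pts))
    E = np.zeros((len(pts), 3))
    tail = np.zeros(len(pts))
    for pos, current_ma in spec.sources:
        pos = np.asarray(pos, dtype=float)
        b = np.linalg.norm(pos)
        if b < 1e-9:
            axis = np.array([0.0, 0.0, 1.0])
        else:
            axis = pos / b
        a, bb, s, C, b_m, inner = _solve_coefficients(spec, b, current_ma * MA)
        R = np.asarray(spec.radii_mm) * MM
        sig = np.asarray(spec.conductivities)
        L = len(R)
        N = spec.n_terms

        r_m = r_pts * MM
        x = np.clip(pts @ axis / np.maximum(r_pts, 1e-30), -1.0, 1.0)
        P, dP = _legendre_with_derivative(x, N)
        layer_idx = np.array([_layer_of(spec, r) for r in r_pts])

        f = np.zeros((N + 1, len(pts)))  # radial profile f_n(r)
        df = np.zeros_like(f)
        for l in np.unique(layer_idx):
            m = layer_idx == l
            r = r_m[m]
            ns = np.arange(1, N + 1)[:, None]
            va = (r[None, :] / R[l]) ** ns
            da = ns * va / r[None, :]
            f[1:, m] += a[l, 1:, None] * va
            df[1:, m] += a[l, 1:, None] * da
            if l < L - 1:
                vb = (inner[l] / r[None, :]) ** (ns + 1)
                db = -(ns + 1) * vb / r[None, :]
                f[1:, m] += bb[l, 1:, None] * vb
                df[1:, m] += bb[l, 1:, None] * db
            if l == s:
                r_lt = np.minimum(r, b_m)
                r_gt = np.maximum(r, b_m)
                ratio = (r_lt / r_gt)[None, :] ** ns
                sv = C * ratio / r_gt[None, :]
                sd = np.where(
                    r[None, :] <= b_m, ns * sv / r[None, :], -(ns + 1) * sv / r[None, :]
                )
                f[1:, m] += sv
                df[1:, m] += sd

        terms = f * P
        phi_src = terms[1:].sum(axis=0)
        denom = np.maximum(np.abs(phi_src), 1e-300)
        tail = np.maximum(tail, np.abs(terms[-1]) / denom)

        # gradient: dphi/dr rhat + f/r * P'(x) (axis - x rhat)
        rhat = pts / np.maximum(r_pts, 1e-30)[:, None]
        radial = (df[1:] * P[1:]).sum(axis=0)
        tang = (f[1:] * dP[1:]).sum(axis=0) / np.maximum(r_m, 1e-30)
        grad = radial[:, None] * rhat + tang[:, None] * (axis[None, :] - x[:, None] * rhat)
        phi += phi_src
        E += -grad

    if np.any(tail > 1e-8):
        raise RuntimeError(
            f"Legendre series not converged (max tail {tail.max():.2e}); increase n_terms"
        )
    return phi, E


def homogeneous_sphere_potential(
    radius_mm: float,
    sigma: float,
    sources: list[tuple[np.ndarray, float]],
    points_mm: np.ndarray,
) -> np.ndarray:
    """Closed-form potential (V) in a homogeneous insulated sphere.

    Independent single-layer check for the series: free-space term plus the
    classical image/log correction obtained from the generating functions
    ``sum t^n P_n = (1 - 2tx + t^2)^(-1/2)`` and
    ``sum t^n P_n / n = log(2 / (1 - tx + sqrt(1 - 2tx + t^2)))``.
    Gauge: the arbitrary n = 0 constant is omitted (compare after centring).
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float)) * MM
    R = radius_mm * MM
    phi = np.zeros(len(pts))
    for pos, current_ma in sources:
        pos = np.asarray(pos, dtype=float) * MM
        I = current_ma * MA
        C = I / (4 * np.pi * sigma)
        b = np.linalg.norm(pos)
        axis = pos / b if b > 0 else np.array([0.0, 0.0, 1.0])
        r = np.linalg.norm(pts, axis=1)
        x = np.clip(pts @ axis / np.maximum(r, 1e-30), -1, 1)
        d = np.linalg.norm(pts - pos, axis=1)
        t = b * r / R**2
        u = np.sqrt(1 - 2 * t * x + t**2)
        # reflected part: C/R * sum_{n>=1} (1 + 1/n) t^n P_n(x)
        sum_tn = 1.0 / u - 1.0
        sum_tn_over_n = np.log(2.0 / (1 - t * x + u))
        phi += C / d + (C / R) * (sum_tn + sum_tn_over_n)
    return phi
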