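"""Hyperbolic plano-convex dielectric lens profile design.

The lens collimates rays from a point feed at the focal distance ``F``: the
feed-facing surface is the hyperbola obtained from the equal-optical-path
condition, and the exit face is planar.  The surface sag measured from the
on-axis vertex is

    t(r) = F/(n+1) * (sqrt(1 + ((n+1)/(n-1)) * (r/F)^2) - 1)

with refractive index ``n = sqrt(eps_r)``.  A brute-force ray-path check of
this closed form is exposed as :func:`optical_path_length`.

Conductivity of the build material is carried along for documentation; it
affects dielectric loss, not the profile shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import C, ChirpConfig, sweep_bandwidth


@dataclass(frozen=True)
class LensSpec:
    """Geometry and material of a hyperbolic collimating lens."""

    focal_length: float           # F [m], feed-to-vertex distance
    radius: float                 # R [m], lens aperture radius
    rel_permittivity: float = 2.68
    conductivity: float = 0.19    # [S/m], loss only; unused by the profile
    design_frequency: float = 79.0e9

    def __post_init__(self) -> None:
        if self.focal_length <= 0:
            raise ValueError("focal_length must be > 0")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.rel_permittivity <= 1:
            raise ValueError("rel_permittivity must be > 1 (need n > 1)")
        if self.design_frequency <= 0:
            raise ValueError("design_frequency must be > 0")

    @property
    def refractive_index(self) -> float:
        return float(np.sqrt(self.rel_permittivity))

    @property
    def design_wavelength(self) -> float:
        return C / self.design_frequency


def default_spec(cfg: ChirpConfig | None = None,
                 frequency: float | None = None) -> LensSpec:
    """Reference lens: R = F = 10 wavelengths, PLA-like material.

    The design wavelength defaults to the centre of the configured sweep
    (or 79 GHz when no configuration is given).
    """
    if frequency is None:
        if cfg is not None:
            frequency = cfg.start_frequency + 0.5 * sweep_bandwidth(cfg)
        else:
            frequency = 79.0e9
    lam = C / frequency
    return LensSpec(focal_length=10.0 * lam, radius=10.0 * lam,
                    rel_permittivity=2.68, conductivity=0.19,
                    design_frequency=frequency)


def thickness(r, spec: LensSpec):
    """Surface sag t(r) of the feed-facing hyperbolic face [m].

    Accepts scalars or arrays; requires 0 <= r <= R.  t(0) = 0 and t is
    strictly increasing, homogeneous of degree one in (r, F) jointly.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > spec.radius * (1 + 1e-12)):
        raise ValueError("r must lie within [0, radius]")
    n = spec.refractive_index
    F = spec.focal_length
    t = F / (n + 1.0) * (np.sqrt(1.0 + (n + 1.0) / (n - 1.0)
                                 * (r_arr / F) ** 2) - 1.0)
    return t if r_arr.ndim else float(t)


def optical_path_length(r, spec: LensSpec):
    """Optical path from the feed to the exit plane for the ray through r.

    Feed at the origin, vertex at z = F, surface at z(r) = F + t(r), exit
    plane at z = F + t(R).  Returns
    ``sqrt(r^2 + z(r)^2) + n * (z_plane - z(r))``, which the collimation
    condition requires to be identical for every r.
    """
    r_arr = np.asarray(r, dtype=float)
    n = spec.refractive_index
    z = spec.focal_length + thickness(r_arr, spec)
    z_plane = spec.focal_length + thickness(spec.radius, spec)
    opl = np.sqrt(r_arr ** 2 + z ** 2) + n * (z_plane - z)
    return opl if r_arr.ndim else float(opl)


def profile_table(spec: LensSpec, n_points: int = 101) -> np.ndarray:
    """Sampled (r, t) profile, shape (n_points, 2), r uniform on [0, R]."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    r = np.linspace(0.0, spec.radius, n_points)
    return np.column_stack([r, thickness(r, spec)])


@dataclass
class ValidityReport:
    """Geometric-optics validity of a lens design."""

    passed: bool
    threshold: float                      # in wavelengths
    radius_wavelengths: float
    min_curvature_radius_wavelengths: float
    warnings: list = field(default_factory=list)


def validity_check(spec: LensSpec, threshold: float = 5.0,
                   n_points: int = 512) -> ValidityReport:
    """Warn when lens dimensions approach the wavelength.

    Checks that the aperture radius and the smallest local radius of
    curvature of the profile both exceed ``threshold`` wavelengths.  A
    failing check produces warnings in the report, never an exception.
    """
    lam = spec.design_wavelength
    r = np.linspace(0.0, spec.radius, n_points)
    t = thickness(r, spec)
    dr = r[1] - r[0]
    dt = np.gradient(t, dr)
    d2t = np.gradient(dt, dr)
    with np.errstate(divide="ignore"):
        curv_radius = (1.0 + dt ** 2) ** 1.5 / np.abs(d2t)
    min_curv = float(np.nanmin(curv_radius))

    warnings = []
    if spec.radius < threshold * lam:
        warnings.append(
            f"aperture radius {spec.radius:.4g} m is below "
            f"{threshold:g} wavelengths ({threshold * lam:.4g} m)")
    if min_curv < threshold * lam:
        warnings.append(
            f"minimum curvature radius {min_curv:.4g} m is below "
            f"{threshold:g} wavelengths ({threshold * lam:.4g} m)")
    return ValidityReport(passed=not warnings, threshold=threshold,
                          radius_wavelengths=spec.radius / lam,
                          min_curvature_radius_wavelengths=min_curv / lam,
                          warnings=warnings)


def export_profile_csv(spec: LensSpec, path, n_points: int = 101) -> None:
    """Write the profile as CSV with columns r_mm, t_mm."""
    table = profile_table(spec, n_points) * 1e3
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("r_mm,t_mm\n")
        for r_mm, t_mm in table:
            fh.write(f"{r_mm:.6f},{t_mm:.6f}\n")


def export_profile_stl(spec: LensSpec, path, n_points: int = 64,
                       n_azimuth: int = 72) -> None:
    """Write the lens solid as an ASCII STL surface of revolution.

    The solid is bounded by the hyperbolic face z = t(r), the planar back
    face z = t(R) and is closed on axis; units are millimetres.
    """
    if n_points < 2 or n_azimuth < 3:
        raise ValueError("need n_points >= 2 and n_azimuth >= 3")
    r = np.linspace(0.0, spec.radius, n_points) * 1e3
    t = thickness(np.linspace(0.0, spec.radius, n_points), spec) * 1e3
    t_back = t[-1]
    phi = np.linspace(0.0, 2.0 * np.pi, n_azimuth + 1)

    def ring(radius_mm, z_mm):
        return np.column_stack([radius_mm * np.cos(phi),
                                radius_mm * np.sin(phi),
                                np.full_like(phi, z_mm)])

    facets = []

    def add_quad(p00, p01, p10, p11):
        facets.append((p00, p01, p11))
        facets.append((p00, p11, p10))

    # curved face
    for i in range(n_points - 1):
        a, b = ring(r[i], t[i]), ring(r[i + 1], t[i + 1])
        for j in range(n_azimuth):
            add_quad(a[j], a[j + 1], b[j], b[j + 1])
    # flat back face (disk at z = t_back)
    rim = ring(r[-1], t_back)
    centre = np.array([0.0, 0.0, t_back])
    for j in range(n_azimuth):
        facets.append((centre, rim[j + 1], rim[j]))

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("solid lens\n")
        for v0, v1, v2 in facets:
            normal = np.cross(v1 - v0, v2 - v0)
            norm = np.linalg.norm(normal)
            normal = normal / norm if norm > 0 else normal
            fh.write(f"  facet normal {normal[0]:.6e} {normal[1]:.6e} "
                     f"{normal[2]:.6e}\n")
            fh.write("    outer loop\n")
            for v in (v0, v1, v2):
                fh.write(f"      vertex {v[0]:.6e} {v[1]:.6e} {v[2]:.6e}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write("endsolid lens\n")
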