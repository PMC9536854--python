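"""Geometry and membrane parameters of the double-cable myelinated axon.

The fiber is the McIntyre–Richardson–Grill (MRG) double-cable mammalian
axon: nodes of Ranvier carrying fast Na+, persistent Na+, slow K+ and leak
conductances, flanked by myelin attachment (MYSA), paranode main (FLUT) and
internode (STIN, six segments) sections whose axolemma is passive and whose
myelin sheath forms the second cable.  Published geometric parameters exist
for fiber diameters of 5.7 µm and above; dorsal-column fibers are smaller
(2.2–8 µm), so geometry below 5.7 µm is obtained by linear extrapolation of
each parameter versus fiber diameter, floored at physical minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MRG_TABLE", "interp_geometry", "AxonModel", "build_axon"]

# Published diameter-dependent geometry (lengths/diameters in µm).
# Columns: fiber diameter, axon (internodal) diameter, node diameter,
# node-to-node spacing, FLUT length, number of myelin lamellae.
MRG_TABLE = {
    "fiber_diameter": np.array([5.7, 7.3, 8.7, 10.0, 11.5, 12.8, 14.0, 15.0, 16.0]),
    "axon_diameter": np.array([3.4, 4.6, 5.8, 6.9, 8.1, 8.9, 10.4, 11.5, 12.7]),
    "node_diameter": np.array([1.9, 2.4, 2.8, 3.3, 3.7, 4.2, 4.7, 5.0, 5.5]),
    "internode_length": np.array([500.0, 750.0, 1000.0, 1150.0, 1250.0, 1350.0, 1400.0, 1450.0, 1500.0]),
    "flut_length": np.array([35.0, 38.0, 40.0, 46.0, 50.0, 54.0, 56.0, 58.0, 60.0]),
    "n_lamellae": np.array([80.0, 100.0, 110.0, 120.0, 130.0, 135.0, 140.0, 145.0, 150.0]),
}

NODE_LENGTH = 1.0  # µm
MYSA_LENGTH = 3.0  # µm
N_STIN = 6

# physical floors for the sub-5.7 µm extrapolation
_FLOORS = {
    "axon_diameter": 1.0,
    "node_diameter": 0.7,
    "flut_length": 10.0,
    "n_lamellae": 30.0,
}
# internode length floor scales with fiber diameter (≈50·D keeps the
# length-to-diameter ratio in the range reported for small myelinated fibers)
_INTERNODE_FLOOR_PER_UM = 50.0

# Electrical constants (MRG values)
RHO_AXIAL = 0.7e6  # Ω·µm axoplasmic and periaxonal resistivity (70 Ω·cm)
CM_AXOLEMMA = 2.0  # µF/cm²
MYELIN_CM_PER_LAMELLA = 0.1  # µF/cm² per membrane (2 membranes per lamella)
MYELIN_GM_PER_LAMELLA = 0.001  # S/cm² per membrane
G_PAS_MYSA = 0.001  # S/cm²
G_PAS_FLUT = 0.0001
G_PAS_STIN = 0.0001
E_PAS = -80.0  # mV
V_REST = -80.0
# periaxonal space widths (µm)
SPACE_NODE = 0.002
SPACE_MYSA = 0.002
SPACE_FLUT = 0.004
SPACE_STIN = 0.004
# the node has no myelin: couple its periaxonal space to the extracellular
# medium through a very large surface conductance
XG_NODE = 1.0e5  # S/cm²

# nodal channel densities (S/cm²) and reversals (mV)
G_NAF = 3.0
G_NAP = 0.01
G_KS = 0.08
G_L = 0.007
E_NA = 50.0
E_K = -90.0
E_L = -90.0

# compartment kind codes
NODE, MYSA, FLUT, STIN = 0, 1, 2, 3


def interp_geometry(fiber_diameter: float) -> dict[str, float]:
    """Diameter-dependent geometry, interpolated from the published table.

    Linear interpolation inside the table; linear extrapolation (from the
    two smallest table entries) below 5.7 µm, floored at physical minima.
    """
    d = float(fiber_diameter)
    if not (2.2 - 1e-9 <= d <= 8.0 + 1e-9):
        raise ValueError(f"fiber diameter {d} µm outside the supported range [2.2, 8] µm")
    d = min(max(d, 2.2), 8.0)
    fd = MRG_TABLE["fiber_diameter"]
    out: dict[str, float] = {"fiber_diameter": d}
    for key in ("axon_diameter", "node_diameter", "internode_length", "flut_length", "n_lamellae"):
        y = MRG_TABLE[key]
        if d >= fd[0]:
            val = float(np.interp(d, fd, y))
        else:
            slope = (y[1] - y[0]) / (fd[1] - fd[0])
            val = float(y[0] + slope * (d - fd[0]))
        if key == "internode_length":
            val = max(val, _INTERNODE_FLOOR_PER_UM * d)
        else:
            val = max(val, _FLOORS[key])
        out[key] = val
    out["stin_length"] = (
        out["internode_length"] - NODE_LENGTH - 2 * MYSA_LENGTH - 2 * out["flut_length"]
    ) / N_STIN
    if out["stin_length"] <= 0:
        raise ValueError("internode too short for the fixed MYSA/FLUT lengths")
    return out


@dataclass
class AxonModel:
    """A discretized double-cable myelinated axon along a 3-D trajectory.

    Arrays are per compartment, ordered node, MYSA, FLUT, 6×STIN, FLUT,
    MYSA, node, …  ``coords_mm`` holds compartment centers used to sample
    the extracellular field.
    """

    fiber_diameter: float
    n_nodes: int
    kind: np.ndarray  # compartment kind codes
    length_um: np.ndarray
    diameter_um: np.ndarray  # axolemma diameter
    coords_mm: np.ndarray  # (n, 3)
    cm_nF: np.ndarray  # axolemma capacitance per compartment
    g_pas_uS: np.ndarray  # axolemma passive conductance (0 at nodes)
    cmy_nF: np.ndarray  # myelin capacitance
    gmy_uS: np.ndarray  # myelin conductance (large at nodes)
    g_axial_uS: np.ndarray  # axoplasmic coupling to next compartment (n-1)
    g_peri_uS: np.ndarray  # periaxonal coupling to next compartment (n-1)
    node_index: np.ndarray  # indices of nodes of Ranvier
    geometry: dict = field(default_factory=dict)
    v_rest: float = V_REST

    @property
    def n_compartments(self) -> int:
        return len(self.kind)

    @property
    def recording_node(self) -> int:
        """Most rostral node of Ranvier (the distal confirmation site)."""
        return int(self.node_index[-1])


def _polyline_points(trajectory: np.ndarray, arclen_um: np.ndarray) -> np.ndarray:
    """Place points at given arclengths (µm) along a polyline given in mm."""
    traj = np.atleast_2d(np.asarray(trajectory, dtype=float))
    if traj.shape[0] < 2 or traj.shape[1] != 3:
        raise ValueError("trajectory must be a polyline of ≥2 3-D points (mm)")
    seg = np.diff(traj, axis=0)
    seg_len = np.linalg.norm(seg, axis=1) * 1e3  # µm
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    if np.any(arclen_um > cum[-1] + 1e-6):
        raise ValueError("trajectory shorter than the axon")
    pts = np.empty((len(arclen_um), 3))
    for i, s in enumerate(arclen_um):
        j = min(np.searchsorted(cum, s, side="right") - 1, len(seg) - 1)
        frac = (s - cum[j]) / seg_len[j]
        pts[i] = traj[j] + frac * seg[j]
    return pts


def build_axon(
    diameter: float,
    trajectory: np.ndarray,
    n_nodes: int = 21,
) -> AxonModel:
    """Build a double-cable axon of the given fiber diameter.

    Parameters
    ----------
    diameter : float
        Fiber (outer) diameter, µm, within [2.2, 8].
    trajectory : (m, 3) array
        Polyline (mm) along which compartments are placed, caudal to
        rostral.  Must be at least ``(n_nodes - 1)`` internodes long.
    n_nodes : int
        Number of nodes of Ranvier (≥21).
    """
    if n_nodes < 21:
        raise ValueError("at least 21 nodes of Ranvier are required")
    geo = interp_geometry(diameter)

    kinds: list[int] = []
    lengths: list[float] = []
    diams: list[float] = []
    inter = [
        (MYSA, MYSA_LENGTH, geo["node_diameter"]),
        (FLUT, geo["flut_length"], geo["axon_diameter"]),
        *[(STIN, geo["stin_length"], geo["axon_diameter"])] * N_STIN,
        (FLUT, geo["flut_length"], geo["axon_diameter"]),
        (MYSA, MYSA_LENGTH, geo["node_diameter"]),
    ]
    for i in range(n_nodes):
        kinds.append(NODE)
        lengths.append(NODE_LENGTH)
        diams.append(geo["node_diameter"])
        if i < n_nodes - 1:
            for k, ln, dm in inter:
                kinds.append(k)
                lengths.append(ln)
                diams.append(dm)
    kind = np.array(kinds, dtype=np.int64)
    length = np.array(lengths)
    diam = np.array(diams)
    n = len(kind)

    centers = np.concatenate([[0.0], np.cumsum(length)])[:-1] + length / 2.0
    coords = _polyline_points(trajectory, centers)

    area_um2 = np.pi * diam * length  # axolemma surface
    cm = CM_AXOLEMMA * area_um2 * 1e-5  # nF

    g_pas_spec = np.zeros(n)
    g_pas_spec[kind == MYSA] = G_PAS_MYSA
    g_pas_spec[kind == FLUT] = G_PAS_FLUT
    g_pas_spec[kind == STIN] = G_PAS_STIN
    g_pas = g_pas_spec * area_um2 * 1e-2  # µS (0 at nodes; nodal channels separate)

    nl = geo["n_lamellae"]
    cmy_spec = np.where(kind == NODE, 0.0, MYELIN_CM_PER_LAMELLA / (2 * nl))
    gmy_spec = np.where(kind == NODE, XG_NODE, MYELIN_GM_PER_LAMELLA / (2 * nl))
    cmy = cmy_spec * area_um2 * 1e-5
    gmy = gmy_spec * area_um2 * 1e-2

    # axial couplings between consecutive compartments (series half-resistances)
    ax_area = np.pi * diam**2 / 4.0  # axoplasm cross-section, µm²
    r_half = RHO_AXIAL * (length / 2.0) / ax_area  # Ω
    g_axial = 1e6 / (r_half[:-1] + r_half[1:])  # µS

    space = np.empty(n)
    space[kind == NODE] = SPACE_NODE
    space[kind == MYSA] = SPACE_MYSA
    space[kind == FLUT] = SPACE_FLUT
    space[kind == STIN] = SPACE_STIN
    peri_area = np.pi * ((diam / 2 + space) ** 2 - (diam / 2) ** 2)
    rp_half = RHO_AXIAL * (length / 2.0) / peri_area
    g_peri = 1e6 / (rp_half[:-1] + rp_half[1:])

    node_index = np.flatnonzero(kind == NODE)
    return AxonModel(
        fiber_diameter=float(diameter),
        n_nodes=n_nodes,
        kind=kind,
        length_um=length,
        diameter_um=diam,
        coords_mm=coords,
        cm_nF=cm,
        g_pas_uS=g_pas,
        cmy_nF=cmy,
        gmy_uS=gmy,
        g_axial_uS=g_axial,
        g_peri_uS=g_peri,
        node_index=node_index,
        geometry=geo,
    )


def straight_trajectory(x_mm: float, y_mm: float, length_mm: float, z0_mm: float | None = None) -> np.ndarray:
    """A straight rostrocaudal path at transverse position (x, y), centered on z=0."""
    if z0_mm is None:
        z0_mm = -length_mm / 2.0
    return np.array([[x_mm, y_mm, z0_mm], [x_mm, y_mm, z0_mm + length_mm]])
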