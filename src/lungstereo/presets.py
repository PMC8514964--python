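"""Reference group means and the synthetic group presets derived from them.

``REFERENCE_TABLE`` holds published design-based stereology reference
values (group mean and between-animal SD, n = 8 lungs per group) for
the preterm-rabbit model of bronchopulmonary dysplasia: pups delivered
three days before term and raised for seven days in 21% O2 (normoxia)
or 95% O2 (hyperoxia).  These numbers serve two purposes here:

* internal-consistency checks — the estimator identities (V = V_V x
  V_ref, tau = 2V/S, Lm = 4V/S, N = N_V x V_ref, ...) must reproduce
  each derived entry from the densities it was computed from;
* parameterizing the synthetic phantom presets, so that a simulated
  two-group cohort reproduces the direction and relative magnitude of
  the normoxia/hyperoxia contrasts.

The phantom is a miniature lung (~7e4 times smaller by volume) built
from spherical cavities, so cavity-lattice parameters cannot take the
table's absolute values: a sphere packing cannot reach the ~86%
airspace fraction of real parenchyma, which couples the feasible
septal thickness to the cavity radius.  The presets therefore keep the
table's *ratios* for septal thickness and number density, share one
alveolar size between groups (mean alveolar volume and Lm did not
differ between groups), and keep vessel dimensions absolute since
individual vessels are resolvable at phantom scale.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq

from .phantom import GroupPreset

#: Table-row keys in report order.  Values are
#: (normoxia mean, normoxia SD, hyperoxia mean, hyperoxia SD).
REFERENCE_TABLE: dict[str, tuple[float, float, float, float]] = {
    "v_lung_cm3": (3.773, 0.437, 2.314, 0.398),
    "vv_par_lung": (0.898, 0.028, 0.809, 0.046),
    "v_par_cm3": (3.392, 0.458, 1.880, 0.380),
    "vv_nonpar_lung": (0.102, 0.028, 0.191, 0.046),
    "v_nonpar_cm3": (0.381, 0.092, 0.434, 0.090),
    "vv_airtot_par": (0.858, 0.034, 0.757, 0.034),
    "v_airtot_cm3": (2.910, 0.408, 1.428, 0.318),
    "vv_airduct_par": (0.274, 0.024, 0.285, 0.042),
    "v_airduct_cm3": (0.931, 0.166, 0.528, 0.095),
    "v_airalv_cm3": (1.979, 0.265, 0.901, 0.275),
    "vv_sept_par": (0.142, 0.034, 0.243, 0.034),
    "v_sept_cm3": (0.482, 0.120, 0.452, 0.092),
    "vv_edema_airtot": (0.027, 0.013, 0.151, 0.050),
    "v_edema_cm3": (0.075, 0.032, 0.208, 0.053),
    "sv_sept_par_cm1": (558.4, 70.55, 475.7, 49.73),
    "s_sept_cm2": (1896.0, 367.0, 893.0, 201.0),
    "tau_sept_um": (5.049, 0.730, 10.26, 1.536),
    "nv_alv_par_cm3": (9.90e6, 0.98e6, 11.22e6, 2.08e6),
    "n_alv": (33.45e6, 4.70e6, 20.72e6, 3.98e6),
    "vn_alv_um3": (60251.0, 11761.0, 45626.0, 20195.0),
    "lm_um": (62.58, 10.50, 64.41, 8.34),
    "vv_lumen_nonpar": (0.17, 0.05, 0.11, 0.03),
    "v_lumen_cm3": (0.061, 0.014, 0.048, 0.011),
    "sv_vasc_lumen_cm1": (537.0, 88.0, 689.0, 133.0),
    "s_vasc_cm2": (32.2, 5.1, 32.7, 10.6),
    "d_vasc_um": (76.3, 12.7, 60.1, 12.1),
    "vv_perivasc_nonpar": (0.086, 0.022, 0.143, 0.029),
    "v_perivasc_cm3": (0.032, 0.010, 0.063, 0.019),
    "vv_vasc_nonpar": (0.042, 0.011, 0.044, 0.009),
    "v_vasc_cm3": (0.015, 0.003, 0.019, 0.005),
    "tau_vasc_um": (4.80, 0.71, 6.03, 1.27),
    "tau_perivasc_um": (9.93, 2.27, 19.53, 4.33),
}

#: Rows for which the hyperoxia group differed significantly (p <= 0.05)
#: from normoxia in the reference data.
REFERENCE_SIGNIFICANT: frozenset[str] = frozenset(
    {
        "v_lung_cm3",
        "vv_par_lung",
        "v_par_cm3",
        "vv_nonpar_lung",
        "vv_airtot_par",
        "v_airtot_cm3",
        "v_airduct_cm3",
        "v_airalv_cm3",
        "vv_sept_par",
        "vv_edema_airtot",
        "v_edema_cm3",
        "sv_sept_par_cm1",
        "s_sept_cm2",
        "tau_sept_um",
        "n_alv",
        "vv_lumen_nonpar",
        "v_lumen_cm3",
        "sv_vasc_lumen_cm1",
        "d_vasc_um",
        "vv_perivasc_nonpar",
        "v_perivasc_cm3",
        "tau_vasc_um",
        "tau_perivasc_um",
    }
)


def _ref(key: str, group: str) -> tuple[float, float]:
    m_n, s_n, m_h, s_h = REFERENCE_TABLE[key]
    return (m_n, s_n) if group == "normoxia" else (m_h, s_h)


def _cv(key: str, group: str) -> float:
    mean, sd = _ref(key, group)
    return sd / mean


# --- phantom-scale anchors -------------------------------------------------
# One normoxia anchor per geometric parameter; the hyperoxia value follows
# from the reference ratio, so group contrasts match the table in relative
# magnitude even where absolute values cannot (see module docstring).
_LUNG_VOLUME_NORMOXIA_UM3 = 5.3e7  # ~ 384 um cube at 1.5 um voxels
# the thickness anchor keeps ~2.5 sigma of between-animal jitter clear of
# the sphere-packing floor (~28 um at this density)
_TAU_SEPT_NORMOXIA_UM = 44.0
_NV_NORMOXIA_PER_UM3 = 4.2e-6  # alveoli per um^3 of parenchyma (pitch ~55 um)
_PAR_FRACTION = {"normoxia": 0.68, "hyperoxia": 0.58}  # bounded by vessel calibre


def _build_preset(group: str) -> GroupPreset:
    ratio = lambda key: _ref(key, group)[0] / _ref(key, "normoxia")[0]  # noqa: E731
    variability = {
        "lung_volume_um3": _cv("v_lung_cm3", group),
        "alveolar_number_density_per_um3": _cv("nv_alv_par_cm3", group),
        "septal_thickness_um": _cv("tau_sept_um", group),
        "parenchymal_fraction": _cv("vv_par_lung", group) / 2.0,
        "edema_airspace_fraction": _cv("vv_edema_airtot", group),
        "vessel_diameter_um": _cv("d_vasc_um", group),
        "vessel_wall_thickness_um": _cv("tau_vasc_um", group),
        "perivascular_thickness_um": _cv("tau_perivasc_um", group),
    }
    return GroupPreset(
        name=group,
        lung_volume_um3=_LUNG_VOLUME_NORMOXIA_UM3 * ratio("v_lung_cm3"),
        parenchymal_fraction=_PAR_FRACTION[group],
        alveolar_number_density_per_um3=_NV_NORMOXIA_PER_UM3 * _nv_ratio(group),
        septal_thickness_um=_TAU_SEPT_NORMOXIA_UM * ratio("tau_sept_um"),
        duct_site_fraction=0.30,
        edema_airspace_fraction=_ref("vv_edema_airtot", group)[0],
        inflammatory_edema_fraction=0.0 if group == "normoxia" else 0.2,
        vessel_diameter_um=_ref("d_vasc_um", group)[0],
        vessel_wall_thickness_um=_ref("tau_vasc_um", group)[0],
        perivascular_thickness_um=_ref("tau_perivasc_um", group)[0],
        vessels_per_lung=2,
        variability=variability,
    )


def _nv_ratio(group: str) -> float:
    """Hyperoxia/normoxia lattice-density ratio.

    With a shared cavity radius (alveolar size did not differ between
    the reference groups) the spherical-lattice identity couples number
    density to septal thickness: doubling tau at constant radius forces
    the lattice pitch up and the density down.  The density ratio is
    therefore derived from the septal-thickness ratio rather than taken
    from the table's (non-significant) N_V contrast.
    """
    if group == "normoxia":
        return 1.0
    tau_n = _TAU_SEPT_NORMOXIA_UM
    tau_h = tau_n * _ref("tau_sept_um", "hyperoxia")[0] / _ref("tau_sept_um", "normoxia")[0]
    pitch_n = (1.0 / (_NV_NORMOXIA_PER_UM3 / 0.70)) ** (1.0 / 3.0)

    def tau_of(pitch: float, r: float) -> float:
        return 2.0 * (pitch**3 - (4.0 / 3.0) * math.pi * r**3) / (4.0 * math.pi * r**2)

    r = brentq(lambda r_: tau_of(pitch_n, r_) - tau_n, 3.0, pitch_n / 2.0 - 1.0)
    pitch_h = brentq(lambda p_: tau_of(p_, r) - tau_h, pitch_n, 4.0 * pitch_n)
    return (pitch_n / pitch_h) ** 3


NORMOXIA = _build_preset("normoxia")
HYPEROXIA = _build_preset("hyperoxia")

PRESETS: dict[str, GroupPreset] = {"normoxia": NORMOXIA, "hyperoxia": HYPEROXIA}


def get_preset(name: str) -> GroupPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
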