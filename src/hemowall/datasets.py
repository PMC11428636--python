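"""Bundled reference data.

``reference_mesh_study`` returns the published mesh-independence summary of
a patient-specific healthy-aorta CFD study: five tetrahedral and five
polyhedral meshes (element sizes 0.2-1.0 mm in 0.2 mm steps) with the
maximum outlet velocity and maximum wall shear stress at peak systole
(t = 0.15 s) and the simulation runtimes.  These tables serve as the
regression fixture for the percentage-difference convention and the
mesh-selection rule in :mod:`hemowall.mesh_sensitivity`.
"""

from __future__ import annotations

from .mesh_sensitivity import MeshStudyRow, MeshStudyTable

__all__ = ["reference_mesh_study", "REFERENCE_SELECTIONS"]

_TETRA = (
    # size_mm, elements, v_max (m/s), wss_max (Pa), runtime (min)
    (0.2, 7_030_641, 0.7200, 21.8233293, 222),
    (0.4, 1_148_142, 0.7075, 22.3736838, 50),
    (0.6, 547_059, 0.6854, 23.0381622, 35),
    (0.8, 405_490, 0.6442, 23.6513115, 31),
    (1.0, 369_728, 0.5607, 26.7444558, 30),
)

_POLY = (
    (0.2, 9_248_899, 0.753678, 19.67837, 103),
    (0.4, 1_753_454, 0.748364, 20.14034, 37),
    (0.6, 951_802, 0.741864, 21.35883, 31),
    (0.8, 766_309, 0.725355, 22.67753, 27),
    (1.0, 732_146, 0.753678, 24.66996, 25),
)

#: Element sizes (mm) the reference study accepts at the 3% threshold.
REFERENCE_SELECTIONS = {
    ("tetrahedral", "v_max"): 0.4,
    ("tetrahedral", "wss_max"): 0.6,
    ("polyhedral", "v_max"): 0.6,
    ("polyhedral", "wss_max"): 0.2,
}

#: Printed integer percentage columns of the reference study, finest row first.
REFERENCE_PERCENT_CELLS = {
    ("tetrahedral", "v_max"): (2, 3, 6, 13),
    ("tetrahedral", "wss_max"): (2, 3, 3, 12),
    ("polyhedral", "v_max"): (1, 1, 2, 4),
    ("polyhedral", "wss_max"): (2, 6, 6, 8),
}


def reference_mesh_study(family: str) -> MeshStudyTable:
    """Reference healthy-aorta mesh study for ``family`` in
    {"tetrahedral", "polyhedral"}."""
    try:
        raw = {"tetrahedral": _TETRA, "polyhedral": _POLY}[family]
    except KeyError:
        raise ValueError(
            f"unknown mesh family {family!r}; expected 'tetrahedral' or 'polyhedral'"
        ) from None
    rows = tuple(
        MeshStudyRow(element_size_mm=s, element_count=n, v_max=v, wss_max=w,
                     runtime_min=t)
        for s, n, v, w, t in raw
    )
    return MeshStudyTable(family=family, rows=rows)
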