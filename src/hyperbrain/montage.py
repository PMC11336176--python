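"""Electrode montage for the 29-channel 10/20 layout used throughout the package.

The recording layout is the 29-electrode subset of the international 10/20
system (Fp1/Fp2, AF3/AF4, F3/F4, F7/F8, FC5/FC6, C3/C4, T7/T8, CP5/CP6,
P3/P4, P7/P8, PO3/PO4, PO7/PO8, O1/O2 plus midline Fz, Cz, Pz). 3-D scalp
positions come from MNE's standard_1020 template montage and are projected
onto the unit sphere, which is all the inverse-great-circle-distance
interpolation needs.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: Default channel order for one participant (29 channels).
CHANNELS_29: tuple[str, ...] = (
    "Fp1", "Fp2", "AF3", "AF4", "F3", "F4", "F7", "F8",
    "FC5", "FC6", "C3", "C4", "T7", "T8", "CP5", "CP6",
    "P3", "P4", "P7", "P8", "PO3", "PO4", "PO7", "PO8",
    "O1", "O2", "Fz", "Cz", "Pz",
)


@lru_cache(maxsize=4)
def _standard_1020_positions() -> dict[str, np.ndarray]:
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    return {name: np.asarray(xyz, dtype=float) for name, xyz in pos.items()}


def channel_positions(labels=CHANNELS_29) -> np.ndarray:
    """Unit-sphere 3-D positions for ``labels``, shape (n_channels, 3).

    Positions are re-centred on the centroid of the full template head and
    normalised to unit length, so great-circle distances on the idealised
    scalp sphere are well defined.
    """
    table = _standard_1020_positions()
    missing = [lab for lab in labels if lab not in table]
    if missing:
        raise KeyError(f"channels not in the standard_1020 montage: {missing}")
    all_xyz = np.array(list(table.values()))
    center = all_xyz.mean(axis=0)
    xyz = np.array([table[lab] for lab in labels]) - center
    norms = np.linalg.norm(xyz, axis=1, keepdims=True)
    return xyz / norms


def great_circle_distances(positions: np.ndarray) -> np.ndarray:
    """Pairwise great-circle (angular) distances between unit vectors, radians."""
    cosine = np.clip(positions @ positions.T, -1.0, 1.0)
    return np.arccos(cosine)
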