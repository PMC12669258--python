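"""Channel layouts: named electrodes with unit-sphere positions.

Algorithms downstream (spherical-spline interpolation, virtual midpoint
channels) only require unit vectors on a sphere, so the default layout uses a
deterministic quasi-uniform spiral over a scalp-like spherical cap with 10-10
system channel names. Positions are synthetic, not measured montage
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ChannelLayout", "make_layout", "TEN_TEN_62"]

#: 10-10 names for the default 62-channel cap (64 minus mastoids M1/M2),
#: ordered roughly front to back.
TEN_TEN_62 = (
    "Fp1 Fpz Fp2 AF7 AF3 AFz AF4 AF8 "
    "F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 "
    "T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 "
    "P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO7 PO3 POz PO4 PO8 O1 Oz O2 Iz"
).split()

MASTOIDS = ("M1", "M2")


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered named electrodes with 3-D unit-sphere positions.

    Parameters
    ----------
    names
        Unique channel identifiers, in data-row order.
    positions
        ``(n_channels, 3)`` array; every row has unit norm (1e-9 tolerance).
    bads
        Channel names flagged bad (to be interpolated / excluded).
    bridged_pairs
        Pairs of channel names detected as electrically bridged.
    """

    names: tuple[str, ...]
    positions: np.ndarray
    bads: frozenset[str] = frozenset()
    bridged_pairs: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        names = tuple(self.names)
        object.__setattr__(self, "names", names)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(names), 3):
            raise ValueError(f"positions must be ({len(names)}, 3), got {pos.shape}")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("channel positions must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)
        bads = frozenset(self.bads)
        unknown = bads - set(names)
        if unknown:
            raise ValueError(f"bad channels not in layout: {sorted(unknown)}")
        object.__setattr__(self, "bads", bads)
        object.__setattr__(
            self, "bridged_pairs", tuple(tuple(p) for p in self.bridged_pairs)
        )

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def good_indices(self) -> np.ndarray:
        return np.array([i for i, n in enumerate(self.names) if n not in self.bads])

    def bad_indices(self) -> np.ndarray:
        return np.array(
            [i for i, n in enumerate(self.names) if n in self.bads], dtype=int
        )

    def with_bads(self, bads) -> "ChannelLayout":
        return replace(self, bads=frozenset(bads))

    def subset(self, names) -> "ChannelLayout":
        """Layout restricted to ``names`` (kept in this layout's order)."""
        keep = [i for i, n in enumerate(self.names) if n in set(names)]
        return ChannelLayout(
            names=tuple(self.names[i] for i in keep),
            positions=self.positions[keep],
            bads=self.bads & set(self.names[i] for i in keep),
        )


def _cap_spiral(n: int, z_min: float = -0.25, z_max: float = 0.995) -> np.ndarray:
    """Deterministic golden-angle spiral over the spherical cap z in [z_min, z_max]."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = np.linspace(z_max, z_min, n)
    phi = golden * np.arange(n)
    r = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def make_layout(n_channels: int = 62, include_mastoids: bool = False) -> ChannelLayout:
    """Build a synthetic scalp layout on the unit sphere.

    ``n_channels == 62`` uses the 10-10 names of a 64-electrode cap minus the
    mastoids; other sizes get generic ``E01..`` names. With
    ``include_mastoids`` two low lateral channels named M1/M2 are appended
    (they are dropped by name before any microstate scoring).
    """
    pos = _cap_spiral(n_channels)
    if n_channels == len(TEN_TEN_62):
        names = tuple(TEN_TEN_62)
    else:
        names = tuple(f"E{i + 1:02d}" for i in range(n_channels))
    if include_mastoids:
        m = np.array([[0.80, 0.35, -0.49], [0.80, -0.35, -0.49]])
        m /= np.linalg.norm(m, axis=1, keepdims=True)
        pos = np.vstack([pos, m])
        names = names + MASTOIDS
    return ChannelLayout(names=names, positions=pos)
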