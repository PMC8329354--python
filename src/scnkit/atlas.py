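"""Cortical parcellation atlases.

The default atlas is the Desikan-Killiany cortical parcellation: 34 gyral
regions per hemisphere, 68 in total, the standard FreeSurfer ``aparc``
labelling used for ROI-level cortical thickness tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["RoiAtlas", "desikan_killiany", "DK_REGIONS"]

#: The 34 Desikan-Killiany gyral labels (FreeSurfer aparc order).
DK_REGIONS: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)


@dataclass(frozen=True)
class RoiAtlas:
    """An ordered, labelled set of cortical regions of interest.

    Parameters
    ----------
    names
        Unique region labels, in canonical order. All thickness tables and
        matrices handled by this package are stored in this order.
    hemispheres
        Per-region hemisphere label, ``"LH"`` or ``"RH"``, aligned with
        ``names``.
    """

    names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.hemispheres):
            raise ValueError("names and hemispheres must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("atlas region names must be unique")
        bad = sorted({h for h in self.hemispheres} - {"LH", "RH"})
        if bad:
            raise ValueError(f"hemisphere labels must be LH/RH, got {bad}")
        object.__setattr__(
            self, "_index", {name: i for i, name in enumerate(self.names)}
        )

    @property
    def n(self) -> int:
        return len(self.names)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        """Position of region ``name`` in canonical order."""
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"region {name!r} is not in the atlas") from None

    def indices(self, names) -> tuple[int, ...]:
        return tuple(self.index(n) for n in names)


def desikan_killiany() -> RoiAtlas:
    """The 68-region Desikan-Killiany atlas, left hemisphere first.

    Region labels follow the ``<hemi>_<region>`` convention used when
    FreeSurfer ROI statistics are exported to tables, e.g. ``lh_insula``.
    """
    names = tuple(f"lh_{r}" for r in DK_REGIONS) + tuple(
        f"rh_{r}" for r in DK_REGIONS
    )
    hemis = ("LH",) * len(DK_REGIONS) + ("RH",) * len(DK_REGIONS)
    return RoiAtlas(names=names, hemispheres=hemis)
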