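"""Binning and labelling configuration for TSR key generation.

A :class:`BinningConfig` fully determines the integer value of every TSR key:
it fixes the vertex label map, the Theta bin boundaries, the MaxDist bin
boundaries, the out-of-range policy and the optional size-gap cutoff and
label-grouping map.  Two key files are only comparable when they were produced
under the same config; every output file records the config hash for that
reason.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

__all__ = [
    "BinningConfig",
    "AMINO_ACID_LABELS",
    "ELEMENT_LABELS",
    "DEFAULT_GROUPING",
    "PHYTOL_TAIL",
    "default_config",
]

#: The 20 standard residues numbered alphabetically by three-letter code.
AMINO_ACID_LABELS: dict[str, int] = {
    name: i + 1
    for i, name in enumerate(
        [
            "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
            "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
            "TYR", "VAL",
        ]
    )
}

# Elements common in pigments and proteins get the low labels; everything else
# follows in atomic-number order so the map is total over elements seen in
# macromolecular files (hydrogen never reaches key generation).
_PRIMARY_ELEMENTS = ["C", "N", "O", "S", "MG", "P", "FE"]
_OTHER_ELEMENTS = [
    "HE", "LI", "BE", "B", "F", "NE", "NA", "AL", "SI", "CL", "AR", "K",
    "CA", "SC", "TI", "V", "CR", "MN", "CO", "NI", "CU", "ZN", "SE", "BR",
    "MO", "I",
]
ELEMENT_LABELS: dict[str, int] = {
    el: i + 1 for i, el in enumerate(_PRIMARY_ELEMENTS + _OTHER_ELEMENTS)
}

#: Residue grouping used by the amino-acid-grouping variant: chemically similar
#: residues share one label (mapped to the smallest member label).
DEFAULT_GROUPING: dict[str, str] = {
    "GLU": "ASP",
    "GLN": "ASN",
    "THR": "SER",
    "LYS": "ARG",
    "LEU": "ILE",
    "VAL": "ILE",
    "TYR": "PHE",
    "TRP": "PHE",
}

#: Chlorophyll phytol-tail carbons excluded by the tail filter.
PHYTOL_TAIL: frozenset[str] = frozenset(f"C{i}" for i in range(6, 21))


def _equal_width(upper: float, n: int) -> tuple[float, ...]:
    return tuple(upper * (i + 1) / n for i in range(n))


@dataclass(frozen=True)
class BinningConfig:
    """Label map plus Theta/MaxDist bin boundaries for one key-generation mode.

    Parameters
    ----------
    mode
        ``"CA"`` (protein backbone, residue-identity labels), ``"COFACTOR"``
        (all heavy atoms of a ligand, element labels) or ``"AA"`` (all heavy
        atoms of one residue, element labels).
    label_map
        Label string -> positive integer.  ``m`` (the encoding base) is the
        maximum value of this map.
    theta_bins, dist_bins
        Strictly increasing upper bin boundaries.  Theta spans (0, 90] degrees;
        MaxDist is in angstroms.  Values beyond the last boundary fall in the
        last bin, values below the first fall in bin 1 (``clamp_overflow``).
    size_gap_cutoff
        Optional MaxDist cutoff in angstroms; triangles with a longer longest
        edge are dropped (the size-gap filter, default cutoff 20 A when used).
    grouping_map
        Optional label -> label remap applied before vertex ordering.
    """

    mode: str
    label_map: dict[str, int]
    theta_bins: tuple[float, ...]
    dist_bins: tuple[float, ...]
    clamp_overflow: bool = True
    size_gap_cutoff: float | None = None
    grouping_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("CA", "COFACTOR", "AA"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for bins, what in ((self.theta_bins, "theta"), (self.dist_bins, "dist")):
            if len(bins) < 1:
                raise ValueError(f"{what}_bins must contain at least one bin")
            if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
                raise ValueError(f"{what}_bins boundaries must strictly increase")
        if not self.label_map:
            raise ValueError("label_map is empty")
        if min(self.label_map.values()) < 1:
            raise ValueError("labels must be positive integers")
        if self.grouping_map is not None:
            unknown = set(self.grouping_map) | set(self.grouping_map.values())
            unknown -= set(self.label_map)
            if unknown:
                raise ValueError(f"grouping_map references unknown labels {sorted(unknown)}")

    # -- derived quantities -------------------------------------------------

    @property
    def m(self) -> int:
        """Encoding base: the number of vertex labels."""
        return max(self.label_map.values())

    @property
    def n_theta(self) -> int:
        return len(self.theta_bins)

    @property
    def n_dist(self) -> int:
        return len(self.dist_bins)

    def effective_label(self, name: str) -> int:
        """Integer label for *name* after applying the grouping map."""
        if self.grouping_map is not None:
            name = self.grouping_map.get(name, name)
        return self.label_map[name]

    def config_hash(self) -> str:
        """Short stable hash identifying this config in output headers."""
        payload = json.dumps(
            {
                "mode": self.mode,
                "label_map": sorted(self.label_map.items()),
                "theta_bins": list(self.theta_bins),
                "dist_bins": list(self.dist_bins),
                "clamp_overflow": self.clamp_overflow,
                "size_gap_cutoff": self.size_gap_cutoff,
                "grouping_map": sorted(self.grouping_map.items())
                if self.grouping_map
                else None,
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def with_(self, **kwargs) -> "BinningConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def default_config(
    mode: str,
    *,
    size_gap_cutoff: float | None = None,
    grouping: bool = False,
) -> BinningConfig:
    """Default :class:`BinningConfig` for a mode.

    Defaults: 30 equal-width Theta bins over (0, 90] in every mode; MaxDist
    bins of 35 x 3 A over (0, 105] for CA, 17 x 1 A for COFACTOR and
    58 x 1 A for AA.  ``grouping=True`` installs the standard amino-acid
    grouping map (CA mode only).
    """
    theta = _equal_width(90.0, 30)
    if mode == "CA":
        dist = _equal_width(105.0, 35)
        labels = AMINO_ACID_LABELS
    elif mode == "COFACTOR":
        dist = _equal_width(17.0, 17)
        labels = ELEMENT_LABELS
    elif mode == "AA":
        dist = _equal_width(58.0, 58)
        labels = ELEMENT_LABELS
    else:
        raise ValueError(f"unknown mode {mode!r}")
    grouping_map = None
    if grouping:
        if mode != "CA":
            raise ValueError("amino-acid grouping applies to CA mode only")
        grouping_map = dict(DEFAULT_GROUPING)
    return BinningConfig(
        mode=mode,
        label_map=dict(labels),
        theta_bins=theta,
        dist_bins=dist,
        size_gap_cutoff=size_gap_cutoff,
        grouping_map=grouping_map,
    )
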