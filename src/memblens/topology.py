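"""Species topology: which atoms anchor each analysis.

A :class:`TopologySpec` maps residue (species) names to their role in the
bilayer and to the named atoms the analyses use as geometric references:

* phospholipids — the ordered carbon lists of each acyl chain (for tilt and
  order parameters) and the phosphate atom (leaflet assignment, depth
  reference, lateral neighbor position);
* sterols — the C3-equivalent carbon (the carbon bearing cholesterol's
  hydroxyl group, or the corresponding carbon of an analog) and an ordered
  head/tail atom pair defining the ring axis for tilt analysis.

Built-in entries cover DPPC, DLiPC, POPS, cholesterol (CHOL) and the
imidazolium-based cholesterol analog CHIM with CHARMM36-style atom names.
User topologies are YAML files with the same schema (see :func:`read_topology`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

__all__ = [
    "SpeciesEntry",
    "TopologySpec",
    "TopologyError",
    "builtin_topology",
    "read_topology",
    "RESNAME_MAP",
    "RESNAME_UNMAP",
]

PHOSPHOLIPID = "phospholipid"
STEROL = "sterol"

#: species name -> residue name used in coordinate files (PDB resName is 4
#: characters wide; "DLiPC" does not fit).  Identity for everything else.
RESNAME_MAP: dict[str, str] = {"DLiPC": "DLIP"}
RESNAME_UNMAP: dict[str, str] = {v: k for k, v in RESNAME_MAP.items()}


class TopologyError(ValueError):
    """Raised when a topology entry is missing or inconsistent."""


@dataclass(frozen=True)
class SpeciesEntry:
    """Role and reference atoms of one lipid species."""

    role: str
    chain_atoms: tuple[tuple[str, ...], ...] = ()
    phosphate_atom: str | None = None
    sterol_ref_atom: str | None = None
    sterol_axis_atoms: tuple[str, str] | None = None

    def validate(self, species: str) -> None:
        if self.role not in (PHOSPHOLIPID, STEROL):
            raise TopologyError(f"{species}: unknown role {self.role!r}")
        names: list[str] = []
        if self.role == PHOSPHOLIPID:
            if not self.chain_atoms:
                raise TopologyError(f"{species}: phospholipid needs chain_atoms")
            for chain in self.chain_atoms:
                if len(chain) < 4:
                    raise TopologyError(
                        f"{species}: chain with {len(chain)} atoms; need >= 4"
                    )
                names.extend(chain)
            if not self.phosphate_atom:
                raise TopologyError(f"{species}: phospholipid needs phosphate_atom")
            names.append(self.phosphate_atom)
        else:
            if not self.sterol_ref_atom:
                raise TopologyError(f"{species}: sterol needs sterol_ref_atom")
            if not self.sterol_axis_atoms or len(self.sterol_axis_atoms) != 2:
                raise TopologyError(
                    f"{species}: sterol needs sterol_axis_atoms (head, tail) pair"
                )
            if self.sterol_axis_atoms[0] == self.sterol_axis_atoms[1]:
                raise TopologyError(f"{species}: sterol axis atoms must differ")
            names.extend([self.sterol_ref_atom, *self.sterol_axis_atoms])
        seen = [n for n in names if names.count(n) > 1]
        # the ref atom may coincide with the axis head atom (C3 plays both
        # parts for cholesterol); any other duplication is an error
        if self.role == STEROL:
            dup = set(seen) - {self.sterol_ref_atom}
            if dup:
                raise TopologyError(f"{species}: duplicate atom names {sorted(dup)}")
        elif seen:
            raise TopologyError(f"{species}: duplicate atom names {sorted(set(seen))}")


@dataclass(frozen=True)
class TopologySpec:
    """Mapping species name -> :class:`SpeciesEntry`."""

    species: Mapping[str, SpeciesEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, entry in self.species.items():
            entry.validate(name)

    def __getitem__(self, species: str) -> SpeciesEntry:
        try:
            return self.species[species]
        except KeyError:
            raise TopologyError(f"species {species!r} not in topology") from None

    def __contains__(self, species: str) -> bool:
        return species in self.species

    def phospholipids(self) -> list[str]:
        return [s for s, e in self.species.items() if e.role == PHOSPHOLIPID]

    def sterols(self) -> list[str]:
        return [s for s, e in self.species.items() if e.role == STEROL]

    def reference_atom(self, species: str) -> str:
        """Lateral/positional reference: phosphate (PL) or C3 carbon (sterol)."""
        entry = self[species]
        if entry.role == PHOSPHOLIPID:
            return entry.phosphate_atom  # type: ignore[return-value]
        return entry.sterol_ref_atom  # type: ignore[return-value]


def _chain(prefix: str, n: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{i}" for i in range(1, n + 1))


def builtin_topology() -> TopologySpec:
    """Default topology for the five supported species.

    Chain atom names follow the CHARMM36 convention of numbering acyl carbons
    C2x (sn-2) and C3x (sn-1) from the carbonyl: DPPC carries two palmitoyl
    (16-carbon) chains, DLiPC two linoleoyl (18-carbon) chains, POPS one
    palmitoyl and one oleoyl chain.  Sterols use C3 (hydroxyl/imidazolium
    carbon) as positional reference and the C3->C17 ring diagonal as axis.
    """
    return TopologySpec(
        {
            "DPPC": SpeciesEntry(
                role=PHOSPHOLIPID,
                chain_atoms=(_chain("C2", 16), _chain("C3", 16)),
                phosphate_atom="P",
            ),
            "DLiPC": SpeciesEntry(
                role=PHOSPHOLIPID,
                chain_atoms=(_chain("C2", 18), _chain("C3", 18)),
                phosphate_atom="P",
            ),
            "POPS": SpeciesEntry(
                role=PHOSPHOLIPID,
                chain_atoms=(_chain("C2", 18), _chain("C3", 16)),
                phosphate_atom="P",
            ),
            "CHOL": SpeciesEntry(
                role=STEROL,
                sterol_ref_atom="C3",
                sterol_axis_atoms=("C3", "C17"),
            ),
            "CHIM": SpeciesEntry(
                role=STEROL,
                sterol_ref_atom="C3",
                sterol_axis_atoms=("C3", "C17"),
            ),
        }
    )


def _parse_entry(species: str, raw: Mapping) -> SpeciesEntry:
    if not isinstance(raw, Mapping):
        raise TopologyError(f"{species}: entry must be a mapping")
    if "role" not in raw:
        raise TopologyError(f"{species}: missing required field 'role'")
    role = raw["role"]
    chains: Sequence[Sequence[str]] = raw.get("chain_atoms", ())
    axis = raw.get("sterol_axis_atoms")
    return SpeciesEntry(
        role=role,
        chain_atoms=tuple(tuple(str(a) for a in c) for c in chains),
        phosphate_atom=raw.get("phosphate_atom"),
        sterol_ref_atom=raw.get("sterol_ref_atom"),
        sterol_axis_atoms=tuple(str(a) for a in axis) if axis else None,  # type: ignore[arg-type]
    )


def read_topology(path: str | Path) -> TopologySpec:
    """Read a YAML topology file, merged over the built-in defaults.

    Schema: a top-level mapping ``species name -> entry`` where an entry has
    ``role`` (``phospholipid`` | ``sterol``) and, by role, ``chain_atoms``
    (list of ordered atom-name lists), ``phosphate_atom``,
    ``sterol_ref_atom`` and ``sterol_axis_atoms`` (ordered [head, tail]).
    Entries for species already built in replace the defaults.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return builtin_topology()
    if not isinstance(raw, Mapping):
        raise TopologyError(f"{path}: topology file must be a mapping")
    merged = dict(builtin_topology().species)
    for species, entry in raw.items():
        merged[str(species)] = _parse_entry(str(species), entry)
    return TopologySpec(merged)


def write_topology(spec: TopologySpec, path: str | Path) -> None:
    """Write a topology spec as YAML (inverse of :func:`read_topology`)."""
    out: dict[str, dict] = {}
    for species, e in spec.species.items():
        d: dict = {"role": e.role}
        if e.chain_atoms:
            d["chain_atoms"] = [list(c) for c in e.chain_atoms]
        if e.phosphate_atom:
            d["phosphate_atom"] = e.phosphate_atom
        if e.sterol_ref_atom:
            d["sterol_ref_atom"] = e.sterol_ref_atom
        if e.sterol_axis_atoms:
            d["sterol_axis_atoms"] = list(e.sterol_axis_atoms)
        out[species] = d
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=True)
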