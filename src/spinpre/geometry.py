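"""Probe placement and probe-nucleus distance tables from complex structures.

Candidate binding modes come as crystal/NMR structures (PDB or mmCIF).  The
spin label itself is never present in those coordinates, so a pseudo-atom
stands in for the nitroxide: either the Cbeta of the cysteine-mutation site
(conservative lower bound) or Cbeta pushed ``extension_length`` Angstrom
further along the Calpha->Cbeta direction to approximate the nitroxide
midpoint of the label's linker.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gemmi
import numpy as np
import pandas as pd

from .model import SpinSystemParams, distance_at_ratio

__all__ = [
    "ProbeSite",
    "BindingMode",
    "DistanceTable",
    "load_structure",
    "place_probe",
    "distance_table",
    "strong_pre_footprint",
]

#: methyl-bearing carbon names considered for atom_role="methyl_C"
_METHYL_CARBONS = {
    "ALA": ("CB",),
    "VAL": ("CG1", "CG2"),
    "LEU": ("CD1", "CD2"),
    "ILE": ("CG2", "CD1"),
    "THR": ("CG2",),
    "MET": ("CE",),
}


@dataclass(frozen=True)
class ProbeSite:
    """Location and placement rule of the spin-label pseudo-atom.

    ``placement_rule`` is "cbeta" (use the Cbeta coordinate; glycine falls
    back to Calpha with a warning) or "cbeta_extended" (Cbeta plus
    ``extension_length`` Angstrom along the Calpha->Cbeta unit vector).
    """

    chain_id: str
    residue_number: int
    placement_rule: str = "cbeta_extended"
    extension_length: float = 7.0

    def __post_init__(self) -> None:
        if self.placement_rule not in ("cbeta", "cbeta_extended"):
            raise ValueError(f"unknown placement_rule {self.placement_rule!r}")
        if self.extension_length < 0:
            raise ValueError("extension_length must be >= 0")


@dataclass(frozen=True)
class BindingMode:
    """A candidate complex structure plus probe site and residue mapping.

    ``chain_map`` translates construct residue numbering (the numbering of
    the observed protein in the experiment) to residue numbers in
    ``observed_chain`` of the structure; identity when omitted.
    """

    name: str
    structure_source: str
    probe: ProbeSite
    observed_chain: str
    chain_map: Mapping[int, int] | None = None

    def __post_init__(self) -> None:
        if self.chain_map is not None:
            targets = list(self.chain_map.values())
            if len(set(targets)) != len(targets):
                raise ValueError("chain_map must be injective")


@dataclass
class DistanceTable:
    """Per-residue probe-nucleus distances for one binding mode.

    ``data`` holds columns (residue_number, atom_role, distance_A); rows are
    unique per (residue_number, atom_role).  ``missing`` lists construct
    residues that could not be measured (absent residue or atom) rather than
    silently dropping them.
    """

    data: pd.DataFrame
    mode_name: str = ""
    placement_rule: str = ""
    missing: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"residue_number", "atom_role", "distance_A"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"DistanceTable requires columns {sorted(required)}")
        if (self.data["distance_A"] <= 0).any():
            raise ValueError("all distances must be strictly positive")
        if self.data.duplicated(["residue_number", "atom_role"]).any():
            raise ValueError("one row per residue + atom_role")

    def distances(self) -> dict[int, float]:
        """Mapping residue_number -> distance (A)."""
        return dict(
            zip(self.data["residue_number"].astype(int), self.data["distance_A"])
        )

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["mode"] = self.mode_name
        out["placement_rule"] = self.placement_rule
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_pairs(
        cls,
        pairs: Mapping[int, float] | Iterable[tuple[int, float]],
        atom_role: str = "amide_N",
        mode_name: str = "",
        placement_rule: str = "",
    ) -> "DistanceTable":
        """Build a table directly from (residue, distance) pairs.

        Used when distances come from an external source (e.g. values read
        off a published analysis) rather than from a structure.
        """
        items = pairs.items() if isinstance(pairs, Mapping) else pairs
        df = pd.DataFrame(
            [(int(res), atom_role, float(d)) for res, d in items],
            columns=["residue_number", "atom_role", "distance_A"],
        )
        return cls(df, mode_name=mode_name, placement_rule=placement_rule)


def load_structure(source: str | Path) -> gemmi.Structure:
    """Read a PDB or mmCIF file into a gemmi Structure.

    Coordinates and author residue numbering are preserved as stored.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse structure {path}: {exc}") from exc
    if len(structure) == 0 or len(structure[0]) == 0:
        raise ValueError(f"structure {path} contains no chains")
    structure.setup_entities()
    return structure


def _find_residue(structure: gemmi.Structure, chain_id: str, residue_number: int):
    model = structure[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = [ch.name for ch in model]
        raise KeyError(f"chain {chain_id!r} not found; structure has {available}")
    for res in chain:
        if res.seqid.num == residue_number:
            return res
    raise KeyError(f"residue {residue_number} not found in chain {chain_id!r}")


def place_probe(structure: gemmi.Structure, site: ProbeSite) -> np.ndarray:
    """Coordinates (A) of the spin-label pseudo-atom for ``site``."""
    res = _find_residue(structure, site.chain_id, site.residue_number)
    ca = res.find_atom("CA", "*")
    if ca is None:
        raise ValueError(
            f"residue {site.residue_number} in chain {site.chain_id!r} has no CA atom"
        )
    ca_pos = np.array([ca.pos.x, ca.pos.y, ca.pos.z])
    cb = res.find_atom("CB", "*")
    if cb is None:
        if res.name == "GLY":
            warnings.warn(
                f"glycine at {site.chain_id}/{site.residue_number}: "
                "no Cbeta, using Calpha for probe placement",
                stacklevel=2,
            )
            return ca_pos
        raise ValueError(
            f"residue {site.residue_number} in chain {site.chain_id!r} has no CB atom"
        )
    cb_pos = np.array([cb.pos.x, cb.pos.y, cb.pos.z])
    if site.placement_rule == "cbeta":
        return cb_pos
    direction = cb_pos - ca_pos
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("degenerate CA/CB geometry at probe site")
    return cb_pos + site.extension_length * direction / norm


def _role_atom(res: gemmi.Residue, atom_role: str):
    """Pick the coordinate for a residue under the requested atom role.

    Returns (position ndarray, effective_role) or None when absent.  For
    methyl_C the nearest methyl carbon is resolved by the caller, which
    receives all candidates.
    """
    if atom_role in ("amide_N", "amide_H"):
        name = "N" if atom_role == "amide_N" else "H"
        atom = res.find_atom(name, "*")
        if atom is None:
            return None
        return np.array([atom.pos.x, atom.pos.y, atom.pos.z]), atom_role
    raise ValueError(f"unknown atom_role {atom_role!r}")


def distance_table(
    structure: gemmi.Structure,
    mode: BindingMode,
    atom_role: str = "amide_N",
) -> DistanceTable:
    """Euclidean probe-nucleus distances for every residue of the observed chain.

    ``atom_role`` is one of "amide_N", "amide_H" or "methyl_C".  amide_H
    rows are emitted only where hydrogens are present in the file; residues
    lacking the requested atom are collected in ``missing``.  For methyl_C
    the nearest methyl carbon of each methyl-bearing residue is used (one
    row per residue).
    """
    if atom_role not in ("amide_N", "amide_H", "methyl_C"):
        raise ValueError(f"unknown atom_role {atom_role!r}")
    probe = place_probe(structure, mode.probe)
    chain = structure[0].find_chain(mode.observed_chain)
    if chain is None or len(chain) == 0:
        raise ValueError(f"observed chain {mode.observed_chain!r} is empty or absent")

    inverse_map = None
    if mode.chain_map is not None:
        inverse_map = {v: k for k, v in mode.chain_map.items()}

    rows: list[tuple[int, str, float]] = []
    missing: list[int] = []
    for res in chain:
        struct_num = res.seqid.num
        if inverse_map is not None:
            if struct_num not in inverse_map:
                continue
            construct_num = inverse_map[struct_num]
        else:
            construct_num = struct_num
        if atom_role == "methyl_C":
            names = _METHYL_CARBONS.get(res.name, ())
            candidates = [res.find_atom(n, "*") for n in names]
            candidates = [a for a in candidates if a is not None]
            if not candidates:
                if res.name in _METHYL_CARBONS:
                    missing.append(construct_num)
                continue
            dists = [
                float(np.linalg.norm(np.array([a.pos.x, a.pos.y, a.pos.z]) - probe))
                for a in candidates
            ]
            rows.append((construct_num, "methyl_C", min(dists)))
        else:
            picked = _role_atom(res, atom_role)
            if picked is None:
                missing.append(construct_num)
                continue
            pos, role = picked
            rows.append((construct_num, role, float(np.linalg.norm(pos - probe))))

    if not rows:
        raise ValueError(
            f"no {atom_role} atoms found in chain {mode.observed_chain!r}"
        )
    df = pd.DataFrame(rows, columns=["residue_number", "atom_role", "distance_A"])
    return DistanceTable(
        df,
        mode_name=mode.name,
        placement_rule=mode.probe.placement_rule,
        missing=missing,
    )


def strong_pre_footprint(
    table: DistanceTable,
    params: SpinSystemParams = SpinSystemParams(),
    threshold: float = 0.4,
    p: float = 1.0,
) -> set[int]:
    """Residues whose predicted ratio at occupancy ``p`` falls below ``threshold``.

    Equivalent to the set of residues closer than
    ``distance_at_ratio(threshold, p)``; empty when p = 0 (no binding means
    no attenuation anywhere).
    """
    if p == 0:
        return set()
    if threshold >= 1.0:
        return set(table.data["residue_number"].astype(int))
    r_cut = distance_at_ratio(threshold, p, params)
    sel = table.data["distance_A"] < r_cut
    return set(table.data.loc[sel, "residue_number"].astype(int))
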