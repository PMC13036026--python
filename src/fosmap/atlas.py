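"""Hierarchical brain atlas: structure ontology plus annotated label volume.

The ontology is a tree of named structures (Allen structure-graph dialect):
broad anatomical divisions are recursively subdivided into finer regions,
nuclei and layers.  Each structure carries its annotated volume in mm^3 and a
gray-matter flag.  The label volume assigns a structure id to every annotated
voxel; label 0 is background and the labelling is hemisphere-symmetric (left
and right counterparts share one id, so they are combined automatically in any
aggregation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "Structure",
    "Ontology",
    "AtlasBundle",
    "OntologyError",
    "load_ontology",
    "write_ontology",
    "exclude_parents",
    "leaf_filter",
]

#: parents may contain unannotated interior volume, but a parent smaller than
#: the sum of its children (beyond this tolerance, mm^3) is a format error
VOLUME_TOLERANCE_MM3 = 1e-6


class OntologyError(ValueError):
    """Malformed structure graph (duplicate ids, multiple roots, cycles...)."""


@dataclass(frozen=True)
class Structure:
    """One node of the structure tree.

    ``depth`` is the number of edges to the root (root = 0); it is always
    recomputed from the parent links, never trusted from a file.
    """

    id: int
    acronym: str
    name: str
    parent_id: int | None
    volume_mm3: float
    is_gray_matter: bool = True
    depth: int = 0

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise OntologyError(f"structure id must be positive, got {self.id}")
        if self.volume_mm3 < 0:
            raise OntologyError(
                f"structure {self.acronym!r}: negative volume {self.volume_mm3}"
            )


class Ontology:
    """Validated structure tree with hierarchy queries.

    Iterating yields structures in depth-first order (children sorted by
    acronym), the canonical column order for wide-format density tables.
    """

    def __init__(self, structures: Iterable[Structure]):
        structures = list(structures)
        ids = [s.id for s in structures]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise OntologyError(f"duplicate structure ids: {dupes}")
        acronyms = [s.acronym for s in structures]
        if len(set(acronyms)) != len(acronyms):
            dupes = sorted({a for a in acronyms if acronyms.count(a) > 1})
            raise OntologyError(f"duplicate acronyms: {dupes}")

        by_id = {s.id: s for s in structures}
        roots = [s for s in structures if s.parent_id is None]
        if len(roots) != 1:
            raise OntologyError(f"expected exactly one root, found {len(roots)}")
        for s in structures:
            if s.parent_id is not None and s.parent_id not in by_id:
                raise OntologyError(
                    f"structure {s.acronym!r} references unknown parent {s.parent_id}"
                )

        # recompute depths by walking parent links; a cycle never reaches root
        depths: dict[int, int] = {roots[0].id: 0}

        def _depth(sid: int, trail: set[int]) -> int:
            if sid in depths:
                return depths[sid]
            if sid in trail:
                raise OntologyError(f"cycle through structure id {sid}")
            trail.add(sid)
            parent = by_id[sid].parent_id
            assert parent is not None
            d = _depth(parent, trail) + 1
            depths[sid] = d
            return d

        for s in structures:
            _depth(s.id, set())

        self._by_id: dict[int, Structure] = {}
        self._by_acronym: dict[str, Structure] = {}
        self._children: dict[int, list[int]] = {s.id: [] for s in structures}
        for s in structures:
            s = Structure(
                id=s.id,
                acronym=s.acronym,
                name=s.name,
                parent_id=s.parent_id,
                volume_mm3=s.volume_mm3,
                is_gray_matter=s.is_gray_matter,
                depth=depths[s.id],
            )
            self._by_id[s.id] = s
            self._by_acronym[s.acronym] = s
        for s in self._by_id.values():
            if s.parent_id is not None:
                self._children[s.parent_id].append(s.id)
        for kids in self._children.values():
            kids.sort(key=lambda i: self._by_id[i].acronym)
        self._root_id = roots[0].id

        for s in self._by_id.values():
            child_sum = sum(self._by_id[c].volume_mm3 for c in self._children[s.id])
            if child_sum > s.volume_mm3 + VOLUME_TOLERANCE_MM3:
                raise OntologyError(
                    f"structure {s.acronym!r}: children volumes sum to "
                    f"{child_sum:.6g} mm^3 > own volume {s.volume_mm3:.6g} mm^3"
                )

    # -- basic queries ----------------------------------------------------

    @property
    def root(self) -> Structure:
        return self._by_id[self._root_id]

    def ids(self) -> list[int]:
        return list(self._by_id)

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, sid: int) -> bool:
        return sid in self._by_id

    def __getitem__(self, key: int | str) -> Structure:
        if isinstance(key, str):
            try:
                return self._by_acronym[key]
            except KeyError:
                raise KeyError(f"unknown acronym {key!r}") from None
        try:
            return self._by_id[key]
        except KeyError:
            raise KeyError(f"unknown structure id {key}") from None

    def __iter__(self) -> Iterator[Structure]:
        yield from (self._by_id[i] for i in self.depth_first_ids())

    def depth_first_ids(self) -> list[int]:
        """Pre-order DFS from the root, children in acronym order."""
        order: list[int] = []
        stack = [self._root_id]
        while stack:
            sid = stack.pop()
            order.append(sid)
            stack.extend(reversed(self._children[sid]))
        return order

    def children(self, sid: int) -> list[int]:
        self[sid]
        return list(self._children[sid])

    def descendants(self, sid: int) -> set[int]:
        """All strict descendants of ``sid`` (transitive closure of children)."""
        self[sid]
        out: set[int] = set()
        stack = list(self._children[sid])
        while stack:
            c = stack.pop()
            out.add(c)
            stack.extend(self._children[c])
        return out

    def ancestors(self, sid: int) -> set[int]:
        out: set[int] = set()
        cur = self[sid].parent_id
        while cur is not None:
            out.add(cur)
            cur = self._by_id[cur].parent_id
        return out

    def is_leaf(self, sid: int) -> bool:
        return not self._children[self[sid].id]

    def leaves(self) -> list[int]:
        return [i for i in self._by_id if self.is_leaf(i)]


# -- serialization ---------------------------------------------------------

def load_ontology(path: str | Path) -> Ontology:
    """Read a flat structure-graph JSON list into a validated :class:`Ontology`.

    Expected record fields: ``id``, ``acronym``, ``name``,
    ``parent_structure_id`` (null for the root), ``volume_mm3``,
    ``gray_matter``.
    """
    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise OntologyError("ontology JSON must be a flat list of records")
    structures = []
    for rec in records:
        try:
            structures.append(
                Structure(
                    id=int(rec["id"]),
                    acronym=str(rec["acronym"]),
                    name=str(rec["name"]),
                    parent_id=(
                        None
                        if rec["parent_structure_id"] is None
                        else int(rec["parent_structure_id"])
                    ),
                    volume_mm3=float(rec["volume_mm3"]),
                    is_gray_matter=bool(rec["gray_matter"]),
                )
            )
        except KeyError as exc:
            raise OntologyError(f"record missing field {exc}") from None
    return Ontology(structures)


def write_ontology(ontology: Ontology, path: str | Path) -> None:
    """Write the flat structure-graph JSON (stable DFS order, 2-space indent)."""
    records = [
        {
            "id": s.id,
            "acronym": s.acronym,
            "name": s.name,
            "parent_structure_id": s.parent_id,
            "volume_mm3": s.volume_mm3,
            "gray_matter": s.is_gray_matter,
        }
        for s in ontology
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)
        fh.write("\n")


# -- region-selection helpers ----------------------------------------------

def exclude_parents(selected: set[int], ontology: Ontology) -> set[int]:
    """Drop every selected structure that has a selected strict descendant.

    Parent and child regions have correlated signal (a parent's counts
    contain its children's), so keeping both in a regression-style analysis
    introduces multicollinearity.  "Descendant" means ANY strict descendant,
    not only direct children, so grandparents cannot leak through.  The
    result is an antichain with respect to ancestry and the operation is
    idempotent.
    """
    unknown = selected - set(ontology.ids())
    if unknown:
        raise KeyError(f"selected ids not in ontology: {sorted(unknown)}")
    return {
        sid for sid in selected if not (ontology.descendants(sid) & selected)
    }


def leaf_filter(ontology: Ontology, min_volume_mm3: float) -> list[int]:
    """Leaves (deepest structures) with volume strictly above the threshold.

    Returned sorted by acronym.  The comparison is strict: a leaf at exactly
    the threshold volume is excluded.
    """
    out = [
        sid
        for sid in ontology.leaves()
        if ontology[sid].volume_mm3 > min_volume_mm3
    ]
    return sorted(out, key=lambda i: ontology[i].acronym)


# -- atlas bundle ----------------------------------------------------------

@dataclass
class AtlasBundle:
    """Ontology paired with its label volume and voxel spacing (z, y, x µm)."""

    ontology: Ontology
    label_volume: np.ndarray
    spacing_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise ValueError("label volume must be 3-D (z, y, x)")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)  # type: ignore[assignment]
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacing_um must be 3 positive reals, got {self.spacing_um}")
        present = np.unique(self.label_volume)
        present = present[present != 0]
        missing = [int(v) for v in present if int(v) not in self.ontology]
        if missing:
            raise OntologyError(f"label volume contains ids not in ontology: {missing}")

    @property
    def voxel_volume_mm3(self) -> float:
        sz, sy, sx = self.spacing_um
        return sz * sy * sx * 1e-9

    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the volume along (z, y, x) in µm."""
        return tuple(n * s for n, s in zip(self.label_volume.shape, self.spacing_um))  # type: ignore[return-value]

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_ontology(self.ontology, directory / "ontology.json")
        tifffile.imwrite(directory / "labels.tif", self.label_volume.astype(np.uint32))
        with open(directory / "spacing.json", "w") as fh:
            json.dump({"spacing_um": list(self.spacing_um), "axis_order": "zyx"}, fh)
            fh.write("\n")

    @classmethod
    def load(cls, directory: str | Path) -> "AtlasBundle":
        directory = Path(directory)
        ontology = load_ontology(directory / "ontology.json")
        labels = tifffile.imread(directory / "labels.tif")
        with open(directory / "spacing.json") as fh:
            spacing = json.load(fh)["spacing_um"]
        return cls(ontology=ontology, label_volume=labels, spacing_um=tuple(spacing))
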