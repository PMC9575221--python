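"""Ligand-receptor interaction database handling.

A ligand-receptor (L-R) database, modeled on CellChatDB, lists signaling
interactions between a ligand and a receptor, either of which may be a
multi-subunit complex (subunits joined by ``+`` in text form).  Tools that
only handle single-subunit interactions need the complexes split, so the
database can be expanded by rearranging every complex into all of its
single-subunit combinations while keeping the original complex entries.
Before spatial scoring, interactions are filtered so that every subunit gene
is detected in a minimum fraction of spots on the slide under study.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Annotation",
    "LRInteraction",
    "LRDatabase",
    "load_database",
    "write_database",
    "expand_multisubunit",
    "filter_by_coverage",
]


class Annotation(str, enum.Enum):
    """Functional category of an interaction (CellChatDB-style)."""

    SECRETED_SIGNALING = "secreted_signaling"
    CELL_CELL_CONTACT = "cell_cell_contact"
    ECM_RECEPTOR = "ecm_receptor"
    OTHER = "other"


_ANNOTATION_ALIASES = {
    "secreted signaling": Annotation.SECRETED_SIGNALING,
    "secreted_signaling": Annotation.SECRETED_SIGNALING,
    "secreted": Annotation.SECRETED_SIGNALING,
    "cell-cell contact": Annotation.CELL_CELL_CONTACT,
    "cell_cell_contact": Annotation.CELL_CELL_CONTACT,
    "cell-cell_contact": Annotation.CELL_CELL_CONTACT,
    "contact": Annotation.CELL_CELL_CONTACT,
    "ecm-receptor": Annotation.ECM_RECEPTOR,
    "ecm_receptor": Annotation.ECM_RECEPTOR,
    "ecm receptor": Annotation.ECM_RECEPTOR,
}


class DatabaseSchemaError(ValueError):
    """Raised when an input table is missing required columns or is empty."""


@dataclass(frozen=True)
class LRInteraction:
    """One ligand-receptor interaction, possibly multi-subunit.

    Parameters
    ----------
    name
        Unique identifier within a database (e.g. ``POSTN_ITGAV_ITGB5``).
    ligand_subunits, receptor_subunits
        Ordered, non-empty gene-symbol lists; input order is preserved for
        display while deduplication keys use a sorted canonical form.
    annotation
        Functional category; unknown strings map to :attr:`Annotation.OTHER`.
    """

    name: str
    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]
    annotation: Annotation = Annotation.OTHER

    def __post_init__(self) -> None:
        for side, subunits in (
            ("ligand", self.ligand_subunits),
            ("receptor", self.receptor_subunits),
        ):
            if len(subunits) == 0:
                raise ValueError(f"{side} subunit list of {self.name!r} is empty")
            if len(set(subunits)) != len(subunits):
                raise ValueError(
                    f"duplicate {side} subunits in {self.name!r}: {subunits}"
                )

    @property
    def ligand(self) -> str:
        """``+``-joined ligand string as written in interchange files."""
        return "+".join(self.ligand_subunits)

    @property
    def receptor(self) -> str:
        return "+".join(self.receptor_subunits)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.ligand_subunits) + tuple(self.receptor_subunits)

    def canonical_key(self) -> tuple[tuple[str, ...], tuple[str, ...]]:
        """Order-insensitive identity of the (ligand, receptor) pairing."""
        return (
            tuple(sorted(self.ligand_subunits)),
            tuple(sorted(self.receptor_subunits)),
        )


@dataclass
class LRDatabase:
    """An ordered collection of unique :class:`LRInteraction` entries."""

    interactions: list[LRInteraction] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        names = [i.name for i in self.interactions]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate interaction names: {dupes}")
        keys = [i.canonical_key() for i in self.interactions]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (ligand, receptor) pairings after canonical ordering")

    def __len__(self) -> int:
        return len(self.interactions)

    def __iter__(self):
        return iter(self.interactions)

    def __getitem__(self, name: str) -> LRInteraction:
        for inter in self.interactions:
            if inter.name == name:
                return inter
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [i.name for i in self.interactions]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interaction_name": [i.name for i in self.interactions],
                "ligand": [i.ligand for i in self.interactions],
                "receptor": [i.receptor for i in self.interactions],
                "annotation": [i.annotation.value for i in self.interactions],
            }
        )


def _parse_annotation(raw: object) -> Annotation:
    text = str(raw).strip().lower()
    return _ANNOTATION_ALIASES.get(text, Annotation.OTHER)


def _split_subunits(raw: object) -> tuple[str, ...]:
    parts = tuple(p.strip() for p in str(raw).split("+") if p.strip())
    return parts


def load_database(path: str | Path, dialect: str = "generic_csv") -> LRDatabase:
    """Load an L-R database from a CSV file.

    The file must carry the header ``interaction_name,ligand,receptor,
    annotation`` with ``+``-joined complex subunits.  Rows that duplicate an
    existing (ligand, receptor) pairing are dropped (first occurrence wins).

    Raises
    ------
    DatabaseSchemaError
        If a required column is missing or the file has no rows.
    """
    if dialect != "generic_csv":
        raise ValueError(f"unknown dialect: {dialect!r}")
    frame = pd.read_csv(path)
    required = {"interaction_name", "ligand", "receptor", "annotation"}
    missing = required - set(frame.columns)
    if missing:
        raise DatabaseSchemaError(f"missing column(s): {sorted(missing)}")
    if frame.empty:
        raise DatabaseSchemaError(f"database file {path} contains no interactions")

    interactions: list[LRInteraction] = []
    seen_keys: set[tuple] = set()
    seen_names: set[str] = set()
    for row in frame.itertuples(index=False):
        inter = LRInteraction(
            name=str(row.interaction_name).strip(),
            ligand_subunits=_split_subunits(row.ligand),
            receptor_subunits=_split_subunits(row.receptor),
            annotation=_parse_annotation(row.annotation),
        )
        key = inter.canonical_key()
        if key in seen_keys:
            continue
        if inter.name in seen_names:
            raise DatabaseSchemaError(
                f"interaction name {inter.name!r} reused for a different gene pairing"
            )
        seen_keys.add(key)
        seen_names.add(inter.name)
        interactions.append(inter)
    return LRDatabase(interactions=interactions, source_label=str(path))


def write_database(db: LRDatabase, path: str | Path) -> None:
    """Write a database back to the interchange CSV dialect."""
    db.to_frame().to_csv(path, index=False)


def _single_subunit_name(ligand: str, receptor: str) -> str:
    return f"{ligand}_{receptor}"


def expand_multisubunit(db: LRDatabase) -> LRDatabase:
    """Split complexes into all single-subunit interactions.

    Every original entry is retained, and for each complex entry every
    (ligand subunit x receptor subunit) combination is appended as a new
    single-subunit interaction, deduplicated against pairings already in
    the database.  Applying the expansion twice gives the same result as
    applying it once.
    """
    out: list[LRInteraction] = list(db.interactions)
    seen = {i.canonical_key() for i in out}
    names = {i.name for i in out}
    for inter in db.interactions:
        if len(inter.ligand_subunits) == 1 and len(inter.receptor_subunits) == 1:
            continue
        for lig in inter.ligand_subunits:
            for rec in inter.receptor_subunits:
                key = ((lig,), (rec,))
                if key in seen:
                    continue
                name = _single_subunit_name(lig, rec)
                while name in names:  # rare symbol clash
                    name += "_split"
                seen.add(key)
                names.add(name)
                out.append(
                    LRInteraction(
                        name=name,
                        ligand_subunits=(lig,),
                        receptor_subunits=(rec,),
                        annotation=inter.annotation,
                    )
                )
    return LRDatabase(interactions=out, source_label=db.source_label)


def gene_spot_fractions(st, genes: Iterable[str]) -> dict[str, float]:
    """Fraction of spots with a nonzero count, per gene.

    ``st`` is a :class:`~spatialcci.tendency.SpatialExpression`; genes absent
    from the slide get fraction 0.0.
    """
    genes = list(genes)
    n_spots = st.n_spots
    fractions: dict[str, float] = {}
    for gene in genes:
        if gene not in st.gene_index:
            fractions[gene] = 0.0
            continue
        row = st.gene_values(gene)
        fractions[gene] = float(np.count_nonzero(row)) / n_spots
    return fractions


def filter_by_coverage(
    db: LRDatabase, st, min_spot_fraction: float = 0.10
) -> LRDatabase:
    """Keep interactions whose every subunit gene is detected broadly enough.

    An interaction survives when EVERY ligand subunit and EVERY receptor
    subunit has nonzero counts in at least ``min_spot_fraction`` of the total
    spots (inclusive threshold).  A complex with any subunit below threshold
    is dropped: the complex cannot be formed without all subunits.
    """
    if st.n_spots < 1:
        raise ValueError("slide has no spots")
    all_genes = {g for inter in db.interactions for g in inter.genes}
    frac = gene_spot_fractions(st, all_genes)
    kept = [
        inter
        for inter in db.interactions
        if all(frac[g] >= min_spot_fraction - 1e-12 for g in inter.genes)
    ]
    return LRDatabase(interactions=kept, source_label=db.source_label)
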