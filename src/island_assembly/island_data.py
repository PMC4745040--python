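"""Data model for island community datasets.

A dataset describes one island (or archipelago treated as a single island):
its age, the size and composition of the mainland species pool, and one
record per independent colonisation.  All times are stored in million years
(My) *before present*; the likelihood machinery converts to forward time
internally.

Five record statuses are distinguished:

1. mainland species with no extant island descendants;
2. non-endemic species present, colonisation time known only as an upper
   bound (``max_age`` is set);
3. non-endemic species present, colonisation time known;
4. endemic species/clade present, mainland relative absent from the island;
5. endemic clade present together with its re-immigrated, non-endemic
   mainland relative.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "STATUSES",
    "ColonistRecord",
    "IslandDataset",
    "ParseError",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "dataset_from_trees",
]

STATUSES = (1, 2, 3, 4, 5)

_TIME_TOL = 1e-9


class ValidationError(ValueError):
    """A dataset or record violates a structural invariant."""


class ParseError(ValueError):
    """A dataset file does not conform to the documented dialect."""


@dataclass(frozen=True)
class ColonistRecord:
    """One independent colonisation of the island.

    Parameters
    ----------
    label
        Free-text identifier, unique within a dataset.
    status
        Data-entry type, 1-5 (see module docstring).
    lineage_class
        Categorical label tying the record to a mainland pool class
        (e.g. ``"DF-type"`` / ``"non-DF-type"``).
    colonisation_time
        Age of the colonisation in My before present.  For status 2 this is
        an upper bound; for status 1 it is absent (``None``).
    branching_times
        Ages of in-situ cladogenesis events of the endemic clade, My before
        present, sorted oldest first.  Empty for statuses 1-3.
    n_missing
        Number of extant island species of this colonist that carry no
        phylogenetic information.
    max_age
        True when ``colonisation_time`` is an upper bound (status 2 only).
    """

    label: str
    status: int
    lineage_class: str
    colonisation_time: float | None = None
    branching_times: tuple[float, ...] = ()
    n_missing: int = 0
    max_age: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "branching_times", tuple(float(b) for b in self.branching_times)
        )
        if self.colonisation_time is not None:
            object.__setattr__(self, "colonisation_time", float(self.colonisation_time))
        self._check()

    # -- invariants -----------------------------------------------------

    def _check(self) -> None:
        lbl = self.label
        if self.status not in STATUSES:
            raise ValidationError(f"record {lbl!r}: unknown status {self.status}")
        if self.n_missing < 0:
            raise ValidationError(f"record {lbl!r}: n_missing must be >= 0")
        if self.status == 1:
            if self.colonisation_time is not None:
                raise ValidationError(
                    f"record {lbl!r}: status 1 carries no colonisation time"
                )
            if self.branching_times:
                raise ValidationError(
                    f"record {lbl!r}: status 1 carries no branching times"
                )
            return
        if self.colonisation_time is None:
            raise ValidationError(
                f"record {lbl!r}: status {self.status} requires a colonisation time"
            )
        if self.colonisation_time <= 0:
            raise ValidationError(
                f"record {lbl!r}: colonisation time must be positive"
            )
        if self.max_age != (self.status == 2):
            raise ValidationError(
                f"record {lbl!r}: max_age must be set exactly for status 2"
            )
        if self.status in (2, 3):
            if self.branching_times:
                raise ValidationError(
                    f"record {lbl!r}: statuses 2-3 carry no branching times"
                )
            return
        # statuses 4 and 5: an endemic clade (possibly a single species)
        bts = self.branching_times
        if list(bts) != sorted(bts, reverse=True):
            raise ValidationError(
                f"record {lbl!r}: branching times must be sorted oldest first"
            )
        if len(set(bts)) != len(bts):
            raise ValidationError(
                f"record {lbl!r}: branching times must be strictly decreasing"
            )
        for b in bts:
            if b <= 0:
                raise ValidationError(
                    f"record {lbl!r}: branching times must be positive"
                )
            if b >= self.colonisation_time - _TIME_TOL:
                raise ValidationError(
                    f"record {lbl!r}: branching time {b} is not younger than the "
                    f"colonisation time {self.colonisation_time}"
                )

    # -- derived quantities ---------------------------------------------

    @property
    def n_in_phylogeny(self) -> int:
        """Number of island lineages represented in the phylogeny at present."""
        if self.status == 1:
            return 0
        if self.status in (2, 3):
            return 1
        return len(self.branching_times) + 1

    @property
    def n_species(self) -> int:
        """Total extant island species implied by the record."""
        extra = 1 if self.status == 5 else 0
        return self.n_in_phylogeny + self.n_missing + extra

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "status": self.status,
            "lineage_class": self.lineage_class,
            "colonisation_time": self.colonisation_time,
            "max_age": self.max_age,
            "branching_times": list(self.branching_times),
            "n_missing": self.n_missing,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColonistRecord":
        try:
            return cls(
                label=str(d["label"]),
                status=int(d["status"]),
                lineage_class=str(d["lineage_class"]),
                colonisation_time=d.get("colonisation_time"),
                branching_times=tuple(d.get("branching_times", ()) or ()),
                n_missing=int(d.get("n_missing", 0)),
                max_age=bool(d.get("max_age", d.get("status") == 2)),
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise ParseError(f"colonist record missing field {exc}") from exc


@dataclass(frozen=True)
class IslandDataset:
    """An island community dataset.

    ``class_fractions`` maps each lineage class to its fraction of the
    mainland pool; fractions must sum to one.
    """

    island_age: float
    M: int
    class_fractions: Mapping[str, float]
    colonists: tuple[ColonistRecord, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "island_age", float(self.island_age))
        object.__setattr__(self, "M", int(self.M))
        object.__setattr__(self, "class_fractions", dict(self.class_fractions))
        object.__setattr__(self, "colonists", tuple(self.colonists))
        self._check()

    def _check(self) -> None:
        if self.island_age <= 0:
            raise ValidationError("island_age must be positive")
        if self.M <= 0:
            raise ValidationError("mainland pool size M must be positive")
        if not self.class_fractions:
            raise ValidationError("at least one lineage class is required")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(
                f"class fractions must sum to 1 (got {total:.6g})"
            )
        for cls, frac in self.class_fractions.items():
            if frac < 0:
                raise ValidationError(f"class {cls!r} has negative fraction")
        labels = [c.label for c in self.colonists]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate colonist labels: {dup}")
        for rec in self.colonists:
            if rec.lineage_class not in self.class_fractions:
                raise ValidationError(
                    f"record {rec.label!r}: unknown lineage class "
                    f"{rec.lineage_class!r}"
                )
            if self.class_fractions[rec.lineage_class] <= 0:
                raise ValidationError(
                    f"record {rec.label!r}: class {rec.lineage_class!r} has zero "
                    "share of the mainland pool"
                )
            if rec.colonisation_time is not None and (
                rec.colonisation_time > self.island_age + _TIME_TOL
            ):
                raise ValidationError(
                    f"record {rec.label!r}: colonisation time "
                    f"{rec.colonisation_time} exceeds island age {self.island_age}"
                )
        for cls in self.class_fractions:
            n_obs = sum(
                1 for r in self.colonists if r.lineage_class == cls and r.status != 1
            )
            share = self.class_fractions[cls] * self.M
            if n_obs > share + 1e-9:
                raise ValidationError(
                    f"class {cls!r}: {n_obs} observed colonists exceed the class "
                    f"share of the mainland pool ({share:.3g})"
                )

    # -- accessors -------------------------------------------------------

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.class_fractions)

    def pool_size(self, lineage_class: str) -> float:
        """Mainland pool share of a class (may be non-integer)."""
        return self.class_fractions[lineage_class] * self.M

    def observed(self, lineage_class: str | None = None) -> tuple[ColonistRecord, ...]:
        """Colonist records with extant descendants (status != 1)."""
        return tuple(
            r
            for r in self.colonists
            if r.status != 1
            and (lineage_class is None or r.lineage_class == lineage_class)
        )

    def max_clade_size(self, lineage_class: str | None = None) -> int:
        sizes = [
            r.n_species
            for r in self.colonists
            if lineage_class is None or r.lineage_class == lineage_class
        ]
        return max(sizes, default=0)

    def total_species(self) -> int:
        return sum(r.n_species for r in self.colonists)

    def to_dict(self) -> dict:
        return {
            "island_age": self.island_age,
            "M": self.M,
            "class_fractions": dict(self.class_fractions),
            "colonists": [c.to_dict() for c in self.colonists],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "IslandDataset":
        for key in ("island_age", "M", "class_fractions"):
            if key not in d:
                raise ParseError(f"dataset is missing required field {key!r}")
        return cls(
            island_age=d["island_age"],
            M=d["M"],
            class_fractions=d["class_fractions"],
            colonists=tuple(
                ColonistRecord.from_dict(r) for r in d.get("colonists", ())
            ),
        )

    def replace(self, **kw) -> "IslandDataset":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "label",
    "status",
    "lineage_class",
    "colonisation_time",
    "max_age",
    "branching_times",
    "n_missing",
)


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt not in ("json", "tsv"):
            raise ValueError(f"unknown dataset format {format!r}")
        return fmt
    return "tsv" if path.suffix.lower() in (".tsv", ".txt") else "json"


def read_dataset(path: str | Path, format: str | None = None) -> IslandDataset:
    """Read and validate an :class:`IslandDataset` from ``path``.

    ``format`` is ``"json"`` (nested records, the primary dialect) or
    ``"tsv"`` (flat spreadsheet export); when omitted it is inferred from
    the file extension.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text()
    if fmt == "json":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON ({exc})") from exc
        if not isinstance(payload, dict):
            raise ParseError(f"{path}: top level must be a JSON object")
        return IslandDataset.from_dict(payload)
    return _read_tsv(path, text)


def _read_tsv(path: Path, text: str) -> IslandDataset:
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
        elif line.strip():
            body.append(line)
    for key in ("island_age", "M"):
        if key not in meta:
            raise ParseError(f"{path}: missing '#{key}=' header line")
    fractions = {
        k.split(":", 1)[1]: float(v)
        for k, v in meta.items()
        if k.startswith("class_fraction:")
    }
    if not fractions:
        raise ParseError(f"{path}: missing '#class_fraction:<class>=' header lines")
    records = []
    reader = csv.DictReader(body, delimiter="\t")
    if reader.fieldnames is None or set(reader.fieldnames) != set(_TSV_COLUMNS):
        raise ParseError(
            f"{path}: TSV header must be {list(_TSV_COLUMNS)}, got {reader.fieldnames}"
        )
    for i, row in enumerate(reader, start=1):
        label = row.get("label") or f"<row {i}>"
        try:
            bts = row["branching_times"].strip()
            records.append(
                ColonistRecord(
                    label=row["label"],
                    status=int(row["status"]),
                    lineage_class=row["lineage_class"],
                    colonisation_time=(
                        float(row["colonisation_time"])
                        if row["colonisation_time"] not in ("", "NA")
                        else None
                    ),
                    max_age=row["max_age"].strip().lower() in ("1", "true", "yes"),
                    branching_times=tuple(
                        float(b) for b in bts.split(";") if b
                    ),
                    n_missing=int(row["n_missing"] or 0),
                )
            )
        except ValidationError:
            raise
        except (ValueError, KeyError) as exc:
            raise ParseError(f"{path}: malformed record {label!r}: {exc}") from exc
    return IslandDataset(
        island_age=float(meta["island_age"]),
        M=int(meta["M"]),
        class_fractions=fractions,
        colonists=tuple(records),
    )


def write_dataset(
    dataset: IslandDataset, path: str | Path, format: str | None = None
) -> None:
    """Write ``dataset`` to ``path``; round-trips through :func:`read_dataset`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(json.dumps(dataset.to_dict(), indent=2) + "\n")
        return
    lines = [f"#island_age={dataset.island_age!r}", f"#M={dataset.M}"]
    for cls, frac in dataset.class_fractions.items():
        lines.append(f"#class_fraction:{cls}={frac!r}")
    lines.append("\t".join(_TSV_COLUMNS))
    for rec in dataset.colonists:
        lines.append(
            "\t".join(
                [
                    rec.label,
                    str(rec.status),
                    rec.lineage_class,
                    "" if rec.colonisation_time is None else repr(rec.colonisation_time),
                    "true" if rec.max_age else "false",
                    ";".join(repr(b) for b in rec.branching_times),
                    str(rec.n_missing),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Newick convenience constructor
# ---------------------------------------------------------------------------


def _node_age(node, max_depth: float) -> float:
    return max_depth - node.distance_from_root()


def _extract_from_tree(
    tree_path: Path,
    island_taxa: Sequence[str],
    conspecific: set[str],
    lineage_class: str,
    label: str,
):
    import dendropy

    tree = dendropy.Tree.get(
        path=str(tree_path), schema="newick", rooting="force-rooted"
    )
    leaves = list(tree.leaf_node_iter())
    depths = [leaf.distance_from_root() for leaf in leaves]
    max_depth = max(depths)
    if max(depths) - min(depths) > 1e-6 * max(max_depth, 1.0):
        raise ValidationError(
            f"{tree_path}: tree is not ultrametric (leaf depths range "
            f"{min(depths):.6g}..{max(depths):.6g})"
        )
    taxa = {leaf.taxon.label: leaf for leaf in leaves if leaf.taxon is not None}
    missing = [t for t in island_taxa if t not in taxa]
    if missing:
        raise ValidationError(f"{tree_path}: island taxa absent from tree: {missing}")
    if len(island_taxa) == len(taxa):
        raise ValidationError(
            f"{tree_path}: no mainland taxa left to anchor the colonisation time"
        )
    island_set = set(island_taxa)
    if len(island_taxa) == 1:
        node = taxa[island_taxa[0]]
    else:
        node = tree.mrca(taxa=[taxa[t].taxon for t in island_taxa])
        clade_leaves = {
            leaf.taxon.label for leaf in node.leaf_iter() if leaf.taxon is not None
        }
        interleaved = sorted(clade_leaves - island_set)
        if interleaved:
            raise ValidationError(
                f"{tree_path}: island taxa are not monophyletic; interleaved "
                f"mainland taxa: {interleaved}"
            )
    if node.parent_node is None:
        raise ValidationError(f"{tree_path}: island clade has no mainland sister")
    stem_age = _node_age(node.parent_node, max_depth)
    branching: list[float] = []
    if len(island_taxa) > 1:
        for internal in node.preorder_iter():
            if not internal.is_leaf():
                branching.append(_node_age(internal, max_depth))
    branching.sort(reverse=True)
    if len(island_taxa) == 1 and island_taxa[0] in conspecific:
        status = 3
    else:
        status = 4
    return ColonistRecord(
        label=label,
        status=status,
        lineage_class=lineage_class,
        colonisation_time=stem_age,
        branching_times=tuple(branching),
        n_missing=0,
    )


def dataset_from_trees(
    newick_paths: Sequence[str | Path],
    island_taxa: Mapping[str, Sequence[str]],
    *,
    island_age: float,
    M: int,
    class_fractions: Mapping[str, float],
    lineage_classes: Mapping[str, str] | None = None,
    conspecific: Iterable[str] = (),
    labels: Mapping[str, str] | None = None,
) -> IslandDataset:
    """Build a dataset from ultrametric, time-calibrated Newick trees.

    One colonist record is extracted per tree.  ``island_taxa`` maps each
    path (as given) to the labels of its island taxa; all remaining taxa are
    treated as mainland relatives.  The colonisation time is the stem age of
    the island clade (the age of its parent node, i.e. the divergence from
    the closest mainland relative) and the branching times are the crown and
    subsequent node ages of the island clade.  A single island taxon listed
    in ``conspecific`` yields a status-3 (non-endemic) record; any other
    extraction yields a status-4 endemic record.
    """
    conspecific = set(conspecific)
    default_class = next(iter(class_fractions))
    records = []
    for p in newick_paths:
        key = str(p)
        if key not in island_taxa:
            raise ValidationError(f"no island taxa declared for tree {key}")
        records.append(
            _extract_from_tree(
                Path(p),
                list(island_taxa[key]),
                conspecific,
                (lineage_classes or {}).get(key, default_class),
                (labels or {}).get(key, Path(p).stem),
            )
        )
    return IslandDataset(
        island_age=island_age,
        M=M,
        class_fractions=class_fractions,
        colonists=tuple(records),
    )
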