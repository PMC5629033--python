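"""Tabular I/O for the interactome / TMT / network pipeline.

Every on-disk format the pipeline touches is plain text with a header row
(TSV by default); XLSX supplements are ingested through a thin adapter onto
the same row schema. Column headers are mapped to roles via a ``columns``
mapping so externally produced tables can be read after a one-line remap.
All writers emit deterministically ordered, fixed-precision output so runs
are byte-reproducible.
"""

from __future__ import annotations


import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "LOCALIZATIONS",
    "FormatError",
    "ValidationError",
    "ProteinRecord",
    "SpectralCountTable",
    "TMTExperiment",
    "FunctionalEdge",
    "AnnotationTable",
    "read_spectral_counts",
    "read_protein_metadata",
    "read_tmt",
    "read_edge_table",
    "read_annotations",
    "write_spectral_counts",
    "write_protein_metadata",
    "write_tmt",
    "write_edge_table",
    "write_annotations",
    "write_reports",
]

#: Recognised subcellular-localization categories.
LOCALIZATIONS = ("nuclear", "unknown", "other")

#: Floats are serialised with 12 significant digits; round-tripping a table
#: therefore reproduces values to 12 significant digits.
FLOAT_FMT = "{:.12g}"


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """Per-protein metadata.

    Parameters
    ----------
    accession : str
        Unique protein identifier.
    gene_symbol : str
        Primary gene symbol (may be empty).
    length_aa : int
        Protein length in amino acids (the NSAF length normaliser), >= 1.
    localization : str
        Subcellular localization class: ``nuclear``, ``unknown`` or ``other``.
    abundance_ppm : float or None
        Estimated whole-cell abundance in parts per million (PAX-style).
        ``None`` means unmeasured; ``0.0`` is a legal measured value and is
        distinct from missing.
    """

    accession: str
    gene_symbol: str
    length_aa: int
    localization: str
    abundance_ppm: float | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("accession must be non-empty")
        if int(self.length_aa) < 1:
            raise ValidationError(
                f"{self.accession}: length_aa must be >= 1, got {self.length_aa}"
            )
        if self.localization not in LOCALIZATIONS:
            raise ValidationError(
                f"{self.accession}: localization {self.localization!r} not in "
                f"{LOCALIZATIONS}"
            )
        if self.abundance_ppm is not None and self.abundance_ppm < 0:
            raise ValidationError(
                f"{self.accession}: abundance_ppm must be >= 0, got {self.abundance_ppm}"
            )


class SpectralCountTable:
    """Bait/control spectral counts and unique-peptide counts per protein.

    Wraps a DataFrame indexed by accession with integer columns
    ``bait_spc``, ``control_spc`` and ``unique_peptides``.
    """

    COLUMNS = ("bait_spc", "control_spc", "unique_peptides")

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate accessions: {dups}")
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {missing}")
        df = df[list(self.COLUMNS)].copy()
        for col in self.COLUMNS:
            vals = df[col]
            if not (vals == vals.astype("int64")).all():
                raise FormatError(f"non-integer values in column {col!r}")
            if (vals < 0).any():
                raise ValidationError(f"negative values in column {col!r}")
            df[col] = vals.astype("int64")
        df.index = df.index.astype(str)
        df.index.name = "accession"
        self.df = df

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, int]]
    ) -> "SpectralCountTable":
        """Build from ``(accession, bait_spc, control_spc, unique_peptides)``."""
        rows = list(records)
        df = pd.DataFrame(
            rows, columns=["accession", *cls.COLUMNS]
        ).set_index("accession")
        return cls(df)

    @property
    def accessions(self) -> list[str]:
        return list(self.df.index)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SpectralCountTable) and self.df.equals(other.df)


class TMTExperiment:
    """TMT reporter abundance matrix with a channel -> (group, replicate) map.

    Parameters
    ----------
    abundances : DataFrame
        Proteins x channels matrix of non-negative reporter abundances,
        indexed by accession.
    channel_map : mapping
        ``channel -> (group, replicate)`` with group in {control, mutant}
        and integer replicate index starting at 1.
    """

    GROUPS = ("control", "mutant")

    def __init__(self, abundances: pd.DataFrame, channel_map: Mapping[str, tuple[str, int]]):
        channel_map = {str(k): (str(v[0]), int(v[1])) for k, v in channel_map.items()}
        missing = [c for c in channel_map if c not in abundances.columns]
        if missing:
            raise FormatError(f"channel(s) {missing} not present in abundance matrix")
        pairs = list(channel_map.values())
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate (group, replicate) pairs in channel_map")
        for group, _ in pairs:
            if group not in self.GROUPS:
                raise ValidationError(f"unknown group {group!r}")
        for group in {g for g, _ in pairs}:
            if sum(1 for g, _ in pairs if g == group) < 2:
                raise ValidationError(f"group {group!r} has fewer than 2 replicates")
        mat = abundances[list(channel_map)].astype(float)
        if (mat.to_numpy() < 0).any():
            raise ValidationError("abundance matrix contains negative entries")
        if mat.index.has_duplicates:
            dups = sorted(mat.index[mat.index.duplicated()].unique())
            raise ValidationError(f"duplicate accessions: {dups}")
        mat.index = mat.index.astype(str)
        mat.index.name = "accession"
        self.abundances = mat
        self.channel_map = channel_map

    def channels_for(self, group: str) -> dict[int, str]:
        """Return ``replicate -> channel`` for one group, sorted by replicate."""
        out = {
            rep: ch for ch, (g, rep) in self.channel_map.items() if g == group
        }
        return dict(sorted(out.items()))

    @property
    def accessions(self) -> list[str]:
        return list(self.abundances.index)

    def __len__(self) -> int:
        return len(self.abundances)


@dataclass(frozen=True)
class FunctionalEdge:
    """An undirected functional-association edge with a confidence score.

    Endpoints are stored in canonical (lexicographic) order so unordered
    pairs compare equal; combined_score lives on [0, 1] (STRING-style
    0-1000 integer scores are rescaled by the reader).
    """

    protein_a: str
    protein_b: str
    combined_score: float

    def __post_init__(self) -> None:
        a, b = str(self.protein_a), str(self.protein_b)
        if a == b:
            raise ValidationError(f"self-loop edge on {a!r}")
        if b < a:
            a, b = b, a
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)
        s = float(self.combined_score)
        if not 0.0 <= s <= 1.0:
            raise ValidationError(f"combined_score {s} outside [0, 1] for ({a}, {b})")
        object.__setattr__(self, "combined_score", s)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


class AnnotationTable:
    """Flat term -> protein annotation records (no ontology propagation)."""

    COLUMNS = ("term_id", "term_name", "accession")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {missing}")
        df = df[list(self.COLUMNS)].astype(str).reset_index(drop=True)
        dup = df.duplicated(subset=["term_id", "accession"])
        if dup.any():
            pairs = df.loc[dup, ["term_id", "accession"]].apply(tuple, axis=1).tolist()
            raise ValidationError(f"duplicate (term_id, accession) pairs: {sorted(set(pairs))}")
        self.df = df

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "AnnotationTable":
        df = pd.DataFrame(list(records), columns=list(cls.COLUMNS))
        return cls(df)

    def proteins_by_term(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for term_id, grp in self.df.groupby("term_id", sort=True):
            out[term_id] = set(grp["accession"])
        return out

    def term_names(self) -> dict[str, str]:
        return dict(zip(self.df["term_id"], self.df["term_name"]))

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_raw_table(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a delimited text file or an XLSX sheet into an all-string frame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path, dtype=str)
    else:
        df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _resolve_columns(
    df: pd.DataFrame, columns: Mapping[str, str], required: Sequence[str]
) -> dict[str, str]:
    resolved = {}
    for role in required:
        header = columns.get(role, role)
        if header not in df.columns:
            raise FormatError(
                f"required column {header!r} (role {role!r}) not found; "
                f"available: {list(df.columns)}"
            )
        resolved[role] = header
    return resolved


def _parse_int(value: str, role: str, accession: str) -> int:
    try:
        as_float = float(value)
    except ValueError:
        raise FormatError(f"{accession}: {role} value {value!r} is not a number") from None
    as_int = int(as_float)
    if as_float != as_int:
        raise FormatError(f"{accession}: {role} value {value!r} is not an integer")
    return as_int


def read_spectral_counts(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> SpectralCountTable:
    """Read a bait/control spectral-count table.

    ``columns`` maps roles (``accession``, ``bait_spc``, ``control_spc``,
    ``unique_peptides``) to the file's header names; by default headers are
    expected to equal the role names. Rows with non-integer counts raise
    :class:`FormatError`; duplicate accessions raise :class:`ValidationError`.
    """
    raw = _read_raw_table(path, delimiter)
    roles = ("accession", *SpectralCountTable.COLUMNS)
    resolved = _resolve_columns(raw, columns or {}, roles)
    records = []
    for _, row in raw.iterrows():
        acc = str(row[resolved["accession"]]).strip()
        counts = tuple(
            _parse_int(str(row[resolved[c]]).strip(), c, acc)
            for c in SpectralCountTable.COLUMNS
        )
        records.append((acc, *counts))
    return SpectralCountTable.from_records(records)


def read_protein_metadata(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> list[ProteinRecord]:
    """Read protein metadata (length, localization, whole-cell abundance).

    Missing abundance is encoded as an empty field in the file and becomes
    ``None``; a literal ``0`` is a measured value.
    """
    raw = _read_raw_table(path, delimiter)
    roles = ("accession", "gene_symbol", "length_aa", "localization", "abundance_ppm")
    resolved = _resolve_columns(raw, columns or {}, roles)
    out = []
    seen: set[str] = set()
    for _, row in raw.iterrows():
        acc = str(row[resolved["accession"]]).strip()
        if acc in seen:
            raise ValidationError(f"duplicate accession {acc!r} in metadata")
        seen.add(acc)
        abund_raw = str(row[resolved["abundance_ppm"]]).strip()
        abundance = None if abund_raw == "" else float(abund_raw)
        out.append(
            ProteinRecord(
                accession=acc,
                gene_symbol=str(row[resolved["gene_symbol"]]).strip(),
                length_aa=_parse_int(str(row[resolved["length_aa"]]).strip(), "length_aa", acc),
                localization=str(row[resolved["localization"]]).strip(),
                abundance_ppm=abundance,
            )
        )
    return out


def read_tmt(
    matrix_path: str | Path,
    channel_map: Mapping[str, tuple[str, int]] | str | Path,
    delimiter: str = "\t",
) -> TMTExperiment:
    """Read a TMT reporter abundance matrix plus its channel map.

    ``channel_map`` is either an in-memory mapping or a path to a JSON file
    of the form ``{"channel": ["control", 1], ...}``.
    """
    if isinstance(channel_map, (str, Path)):
        with open(channel_map) as fh:
            loaded = json.load(fh)
        channel_map = {k: (v[0], int(v[1])) for k, v in loaded.items()}
    raw = _read_raw_table(matrix_path, delimiter)
    if "accession" not in raw.columns:
        raise FormatError("TMT matrix must have an 'accession' column")
    raw = raw.set_index("accession")
    for ch in channel_map:
        if ch not in raw.columns:
            raise FormatError(f"channel column {ch!r} missing from matrix")
        raw[ch] = raw[ch].astype(float)
    return TMTExperiment(raw, channel_map)


def read_edge_table(
    path: str | Path,
    score_scale: str = "auto",
    columns: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> list[FunctionalEdge]:
    """Read a functional-association edge table (STRING dialect tolerated).

    ``score_scale`` is one of ``auto`` / ``unit`` / ``milli``: under ``auto``,
    if any score exceeds 1 the whole column is treated as a 0-1000 integer
    STRING score and divided by 1000. Self-loops are dropped with a warning;
    unordered duplicate pairs are collapsed keeping the maximum score.
    """
    if score_scale not in ("auto", "unit", "milli"):
        raise ValueError(f"unknown score_scale {score_scale!r}")
    raw = _read_raw_table(path, delimiter)
    resolved = _resolve_columns(
        raw, columns or {}, ("protein_a", "protein_b", "combined_score")
    )
    scores = raw[resolved["combined_score"]].astype(float)
    if score_scale == "milli" or (score_scale == "auto" and len(scores) and scores.max() > 1.0):
        scores = scores / 1000.0
    best: dict[tuple[str, str], float] = {}
    for (_, row), score in zip(raw.iterrows(), scores):
        a = str(row[resolved["protein_a"]]).strip()
        b = str(row[resolved["protein_b"]]).strip()
        if a == b:
            warnings.warn(f"dropping self-loop edge on {a!r}", stacklevel=2)
            continue
        if not 0.0 <= score <= 1.0:
            raise ValidationError(
                f"combined_score {score} outside [0, 1] for ({a}, {b}) after scaling"
            )
        key = (a, b) if a < b else (b, a)
        if key not in best or score > best[key]:
            best[key] = float(score)
    return [
        FunctionalEdge(a, b, s) for (a, b), s in sorted(best.items())
    ]


def read_annotations(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    delimiter: str = "\t",
) -> AnnotationTable:
    """Read a flat (term_id, term_name, accession) annotation table."""
    raw = _read_raw_table(path, delimiter)
    resolved = _resolve_columns(raw, columns or {}, AnnotationTable.COLUMNS)
    df = raw[[resolved[c] for c in AnnotationTable.COLUMNS]]
    df.columns = list(AnnotationTable.COLUMNS)
    return AnnotationTable(df)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _jsonable(value):
    if isinstance(value, (set, frozenset)):
        return sorted(value)
    return str(value)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return FLOAT_FMT.format(value)
    return str(value)


def _write_tsv(path: Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_spectral_counts(table: SpectralCountTable, path: str | Path) -> None:
    rows = (
        (acc, *[int(v) for v in row])
        for acc, row in table.df.sort_index().iterrows()
    )
    _write_tsv(Path(path), ("accession", *SpectralCountTable.COLUMNS), rows)


def write_protein_metadata(records: Sequence[ProteinRecord], path: str | Path) -> None:
    rows = (
        (r.accession, r.gene_symbol, r.length_aa, r.localization, r.abundance_ppm)
        for r in sorted(records, key=lambda r: r.accession)
    )
    _write_tsv(
        Path(path),
        ("accession", "gene_symbol", "length_aa", "localization", "abundance_ppm"),
        rows,
    )


def write_tmt(tmt: TMTExperiment, matrix_path: str | Path, channels_path: str | Path) -> None:
    channels = list(tmt.abundances.columns)
    rows = (
        (acc, *[float(v) for v in row])
        for acc, row in tmt.abundances.sort_index().iterrows()
    )
    _write_tsv(Path(matrix_path), ("accession", *channels), rows)
    with open(channels_path, "w") as fh:
        json.dump({ch: list(gr) for ch, gr in tmt.channel_map.items()}, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_edge_table(edges: Sequence[FunctionalEdge], path: str | Path) -> None:
    rows = (
        (e.protein_a, e.protein_b, e.combined_score)
        for e in sorted(edges, key=lambda e: e.pair)
    )
    _write_tsv(Path(path), ("protein_a", "protein_b", "combined_score"), rows)


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    df = table.df.sort_values(["term_id", "accession"], kind="mergesort")
    _write_tsv(Path(path), AnnotationTable.COLUMNS, df.itertuples(index=False))


def _network_to_sif(graph: nx.Graph, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\tpp\t{b}\n")
        for node in sorted(graph.nodes()):
            if graph.degree(node) == 0:
                fh.write(f"{node}\n")


def write_reports(
    results: Mapping[str, object],
    out_dir: str | Path,
    config: Mapping[str, object] | None = None,
    seed: int | None = None,
) -> dict[str, str]:
    """Write every recognised pipeline product in ``results`` to ``out_dir``.

    Recognised keys: ``candidates`` (ranked InteractionCandidate sequence),
    ``differential`` (DifferentialCall sequence), ``network``
    (FunctionalNetwork), ``enrichment`` (EnrichmentResult sequence). A JSON
    run manifest with the config hash and seed is always written. Returns a
    ``product -> filename`` manifest. Outputs are byte-stable for identical
    inputs and config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    if "candidates" in results:
        cands = results["candidates"]  # type: ignore[index]
        rows = [
            (
                c.rank,
                c.accession,
                c.bait_spc,
                c.control_spc,
                c.fold_enrichment,
                c.nsaf,
                c.enrichment_index,
            )
            for c in sorted(cands, key=lambda c: (c.rank if c.rank else 10**9, c.accession))
        ]
        _write_tsv(
            out / "candidates.tsv",
            ("rank", "accession", "bait_spc", "control_spc", "fold", "nsaf", "enrichment_index"),
            rows,
        )
        manifest["candidates"] = "candidates.tsv"

    if "differential" in results:
        calls = results["differential"]  # type: ignore[index]
        rows = [
            (c.accession, c.ratio_rep1, c.ratio_rep2, c.mean_ratio, c.direction)
            for c in sorted(calls, key=lambda c: c.accession)
        ]
        _write_tsv(
            out / "differential.tsv",
            ("accession", "ratio_rep1", "ratio_rep2", "mean_ratio", "direction"),
            rows,
        )
        manifest["differential"] = "differential.tsv"

    if "network" in results:
        net = results["network"]  # type: ignore[index]
        graph = net.graph if hasattr(net, "graph") else net
        nx.write_graphml(graph, out / "network.graphml")
        _network_to_sif(graph, out / "network.sif")
        manifest["network"] = "network.graphml"
        manifest["network_sif"] = "network.sif"

    if "enrichment" in results:
        enr = results["enrichment"]  # type: ignore[index]
        rows = [
            (r.term_id, r.term_name, r.k, r.K, r.n, r.N, r.p_value, r.q_value, r.up_fraction)
            for r in sorted(enr, key=lambda r: (r.p_value, r.term_id))
        ]
        _write_tsv(
            out / "enrichment.tsv",
            ("term_id", "term_name", "k", "K", "n", "N", "p_value", "q_value", "up_fraction"),
            rows,
        )
        manifest["enrichment"] = "enrichment.tsv"

    config = dict(config or {})
    config_json = json.dumps(config, sort_keys=True, default=_jsonable)
    run_manifest = {
        "files": manifest,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": seed,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest["manifest"] = "manifest.json"
    return manifest
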