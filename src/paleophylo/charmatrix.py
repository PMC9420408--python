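"""Morphological character matrices and biogeographic coding.

Covers assembly of the analysis-ready supermatrix: concatenation of source
matrices with duplication balancing, removal of invariant columns,
longitudinal-zone coding of occurrence localities, and splitting of
multi-locality taxa into dated operational taxonomic units (OTUs) with
uniform tip-age priors and clade constraints.

States are small non-negative integers (0-9); missing data is ``'?'``
(stored internally as -1).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "CharacterMatrix",
    "Zone",
    "ZoneScheme",
    "default_zone_scheme",
    "OccurrenceRecord",
    "Otu",
    "OtuExpansion",
    "concat_with_duplication",
    "remove_invariant_columns",
    "assign_zone",
    "zone_for_taxon",
    "append_zone_character",
    "split_multilocality_otus",
    "geocentroid",
    "read_occurrences_csv",
    "write_occurrences_csv",
]

MISSING = -1  # internal code for '?'
SYMBOLS = "0123456789"


# ---------------------------------------------------------------------------
# CharacterMatrix
# ---------------------------------------------------------------------------


class CharacterMatrix:
    """Rectangular taxa x characters matrix of discrete states.

    Parameters
    ----------
    taxa : ordered taxon labels.
    data : (n_taxa, n_char) integer array; -1 encodes missing ('?').
    ordered : per-character bool flags (adjacent-state transitions only).
    partition : per-character partition ids (contiguous per block).
    source : per-character source-matrix labels.
    """

    def __init__(self, taxa, data, ordered=None, partition=None, source=None):
        self.taxa: list[str] = list(taxa)
        self.data = np.asarray(data, dtype=np.int16)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("data must be (n_taxa, n_char)")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        n = self.n_char
        self.ordered = (
            np.zeros(n, dtype=bool) if ordered is None
            else np.asarray(ordered, dtype=bool)
        )
        self.partition = (
            np.zeros(n, dtype=int) if partition is None
            else np.asarray(partition, dtype=int)
        )
        self.source = list(source) if source is not None else [None] * n
        if not (len(self.ordered) == len(self.partition) == len(self.source) == n):
            raise ValueError("per-character metadata length mismatch")
        if self.data.size and (self.data.max() > 9 or self.data.min() < -1):
            raise ValueError("states must be 0-9 or missing (-1)")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_char(self) -> int:
        return self.data.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.data[self.taxa.index(taxon)]

    def column(self, j: int) -> np.ndarray:
        return self.data[:, j]

    def character_dict(self, j: int) -> dict[str, Optional[int]]:
        """Taxon -> state (None for missing) for one character; the input
        form the ancestral-reconstruction routines accept."""
        col = self.data[:, j]
        return {
            t: (None if s == MISSING else int(s))
            for t, s in zip(self.taxa, col)
        }

    def copy(self) -> "CharacterMatrix":
        return CharacterMatrix(
            self.taxa,
            self.data.copy(),
            self.ordered.copy(),
            self.partition.copy(),
            list(self.source),
        )

    def partition_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.partition, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    # -- NEXUS I/O ---------------------------------------------------------

    def to_nexus(self, include_charsets: bool = True) -> str:
        max_state = int(self.data.max()) if self.data.size else 0
        symbols = SYMBOLS[: max(max_state + 1, 2)]
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"    DIMENSIONS NTAX={self.n_taxa} NCHAR={self.n_char};",
            f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
            "    MATRIX",
        ]
        width = max(len(t) for t in self.taxa) + 2
        for i, taxon in enumerate(self.taxa):
            row = "".join(
                "?" if s == MISSING else str(int(s)) for s in self.data[i]
            )
            lines.append(f"    {taxon.ljust(width)}{row}")
        lines.append("    ;")
        lines.append("END;")
        if include_charsets and self.n_char:
            lines.append("BEGIN SETS;")
            for pid in sorted(set(self.partition.tolist())):
                idx = np.flatnonzero(self.partition == pid) + 1  # 1-based
                lines.append(
                    f"    CHARSET partition_{pid} = {_ranges(idx)};"
                )
            lines.append("END;")
            ordered_idx = np.flatnonzero(self.ordered) + 1
            if ordered_idx.size:
                lines.append(
                    f"[ordered characters: {_ranges(ordered_idx)}]"
                )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_nexus(cls, source: str) -> "CharacterMatrix":
        """Read a NEXUS DATA/CHARACTERS block (via dendropy)."""
        import dendropy

        if "\n" in source or source.lstrip().upper().startswith("#NEXUS"):
            mat = dendropy.StandardCharacterMatrix.get(
                file=io.StringIO(source), schema="nexus",
                preserve_underscores=True,
            )
        else:
            mat = dendropy.StandardCharacterMatrix.get(
                path=source, schema="nexus", preserve_underscores=True
            )
        taxa = ["_".join(t.label.split()) for t in mat.taxon_namespace]
        rows = []
        for taxon in mat.taxon_namespace:
            seq = mat[taxon]
            row = []
            for cell in seq.symbols_as_list():
                row.append(MISSING if cell in "?-" else int(cell))
            rows.append(row)
        return cls(taxa, np.array(rows, dtype=np.int16))

    def mrbayes_block(self, expansion: Optional["OtuExpansion"] = None) -> str:
        """Emit a reference MrBayes-style text block: charset/ctype lines
        plus (if an OTU expansion is supplied) clade constraints and
        uniform tip-age calibrations.  For human inspection only."""
        lines = ["begin mrbayes;"]
        for pid in sorted(set(self.partition.tolist())):
            idx = np.flatnonzero(self.partition == pid) + 1
            lines.append(f"  charset part{pid} = {_ranges(idx)};")
        ordered_idx = np.flatnonzero(self.ordered) + 1
        if ordered_idx.size:
            lines.append(f"  ctype ordered: {_ranges(ordered_idx)};")
        if expansion is not None:
            for i, group in enumerate(expansion.clade_constraints, 1):
                labels = " ".join(sorted(group))
                lines.append(f"  constraint split{i} = {labels};")
            for otus in expansion.mapping.values():
                for otu in otus:
                    lo, hi = otu.age_range
                    lines.append(
                        f"  calibrate {otu.label} = uniform({lo:g},{hi:g});"
                    )
        lines.append("end;")
        return "\n".join(lines) + "\n"


def _ranges(indices: np.ndarray) -> str:
    """Compact 1-based index list to NEXUS range notation."""
    out = []
    run_start = prev = int(indices[0])
    for i in indices[1:]:
        i = int(i)
        if i == prev + 1:
            prev = i
            continue
        out.append(f"{run_start}-{prev}" if prev > run_start else f"{run_start}")
        run_start = prev = i
    out.append(f"{run_start}-{prev}" if prev > run_start else f"{run_start}")
    return " ".join(out)


# ---------------------------------------------------------------------------
# Concatenation with duplication balancing
# ---------------------------------------------------------------------------


def concat_with_duplication(
    matrices: Sequence[CharacterMatrix],
    factors: Sequence[int],
    physical: bool = True,
) -> tuple[CharacterMatrix, list[int]]:
    """Concatenate source matrices, repeating each matrix's character block
    ``factor`` times to balance partition sizes.

    Each source matrix becomes one partition whose size is
    ``n_char * factor``.  Taxa are unioned; a taxon absent from a source
    matrix gets all-missing cells in that partition.  Duplicated columns are
    tagged so downstream character statistics can deduplicate: with
    ``physical=False`` only metadata is built and each character appears
    once (the duplication exists solely to upweight likelihood signal in
    tree searches).

    Returns the combined matrix and the list of partition sizes.
    """
    if len(matrices) != len(factors):
        raise ValueError("one duplication factor per matrix required")
    if any(f < 1 or int(f) != f for f in factors):
        raise ValueError("factors must be positive integers")
    all_taxa: list[str] = []
    for m in matrices:
        for t in m.taxa:
            if t not in all_taxa:
                all_taxa.append(t)
    blocks, ordered, partition, source, sizes = [], [], [], [], []
    for pid, (m, f) in enumerate(zip(matrices, factors)):
        reps = int(f) if physical else 1
        sizes.append(m.n_char * int(f))
        block = np.full((len(all_taxa), m.n_char * reps), MISSING, np.int16)
        row_of = {t: i for i, t in enumerate(m.taxa)}
        for i, t in enumerate(all_taxa):
            if t in row_of:
                block[i] = np.tile(m.data[row_of[t]], reps)
        blocks.append(block)
        ordered.extend(list(m.ordered) * reps)
        partition.extend([pid] * m.n_char * reps)
        src = m.source if any(s is not None for s in m.source) else [pid] * m.n_char
        source.extend(list(src) * reps)
    data = np.hstack(blocks) if blocks else np.zeros((len(all_taxa), 0), np.int16)
    out = CharacterMatrix(all_taxa, data, ordered, partition, source)
    return out, sizes


def remove_invariant_columns(
    matrix: CharacterMatrix,
) -> tuple[CharacterMatrix, list[int]]:
    """Drop every column whose set of observed (non-missing) states has
    size <= 1; required by ascertainment-bias ('variable') coding.
    Returns the reduced matrix and the removed column indices."""
    removed = []
    for j in range(matrix.n_char):
        col = matrix.data[:, j]
        observed = set(col[col != MISSING].tolist())
        if len(observed) <= 1:
            removed.append(j)
    keep = [j for j in range(matrix.n_char) if j not in set(removed)]
    out = CharacterMatrix(
        matrix.taxa,
        matrix.data[:, keep],
        matrix.ordered[keep],
        matrix.partition[keep],
        [matrix.source[j] for j in keep],
    )
    return out, removed


# ---------------------------------------------------------------------------
# Longitudinal zone scheme
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Zone:
    code: int
    lon_min: float  # inclusive
    lon_max: float  # exclusive
    name: str = ""

    @property
    def width(self) -> float:
        w = self.lon_max - self.lon_min
        return w if w > 0 else w + 360.0

    def contains(self, lon: float) -> bool:
        if self.lon_min < self.lon_max:
            return self.lon_min <= lon < self.lon_max
        # dateline-crossing zone: [lon_min, 180] u (-180, lon_max)
        return lon >= self.lon_min or lon < self.lon_max


@dataclass(frozen=True)
class ZoneScheme:
    zones: tuple[Zone, ...]

    def __post_init__(self):
        total = sum(z.width for z in self.zones)
        if abs(total - 360.0) > 1e-9:
            raise ValueError(
                f"zones must tile the circle exactly once (widths sum to {total})"
            )
        codes = [z.code for z in self.zones]
        if codes != sorted(codes) or len(set(codes)) != len(codes):
            raise ValueError("zone codes must be unique and ordered")

    @property
    def codes(self) -> list[int]:
        return [z.code for z in self.zones]

    def adjacent(self, a: int, b: int) -> bool:
        return abs(a - b) == 1


def default_zone_scheme() -> ZoneScheme:
    """The five contiguous longitudinal zones used for biogeographic coding
    of sea-cow occurrence localities.  Zone 0 crosses the dateline.
    Intervals are half-open ``[lon_min, lon_max)`` west to east; a boundary
    longitude belongs to the zone whose lower bound it equals."""
    return ZoneScheme((
        Zone(0, 130.0, -160.0, "Far East Asia and Beringia"),
        Zone(1, -160.0, -100.0, "western North America"),
        Zone(2, -100.0, -25.0, "eastern North America, South America, Caribbean"),
        Zone(3, -25.0, 60.0, "Europe and Africa"),
        Zone(4, 60.0, 130.0, "Pan Asia (excluding the Far East)"),
    ))


def assign_zone(lon: float, scheme: Optional[ZoneScheme] = None) -> int:
    """Bin a longitude into its zone code.  Total and single-valued on
    (-180, 180]."""
    if scheme is None:
        scheme = default_zone_scheme()
    if not (-180.0 < lon <= 180.0):
        raise ValueError(f"longitude {lon} outside (-180, 180]")
    hits = [z.code for z in scheme.zones if z.contains(lon)]
    if len(hits) != 1:  # pragma: no cover - guarded by scheme validation
        raise ValueError(f"scheme does not uniquely bin longitude {lon}")
    return hits[0]


# ---------------------------------------------------------------------------
# Occurrences & OTU splitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OccurrenceRecord:
    """One fossil locality (or extant range sample point)."""

    taxon: str
    locality_id: str
    lon: float  # WGS84 decimal degrees, (-180, 180]
    lat: float  # [-90, 90]
    age_min: float  # Ma
    age_max: float  # Ma
    map_id: Optional[str] = None

    def __post_init__(self):
        if self.age_min > self.age_max:
            raise ValueError("age_min > age_max")
        if not (-180.0 < self.lon <= 180.0):
            raise ValueError(f"lon {self.lon} outside (-180, 180]")
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"lat {self.lat} outside [-90, 90]")

    @property
    def age_mid(self) -> float:
        return 0.5 * (self.age_min + self.age_max)


def read_occurrences_csv(path_or_buf) -> list[OccurrenceRecord]:
    df = pd.read_csv(path_or_buf)
    recs = []
    for i, row in df.iterrows():
        recs.append(OccurrenceRecord(
            taxon="_".join(str(row["taxon"]).split()),
            locality_id=str(row.get("locality_id", i)),
            lon=float(row["lon"]),
            lat=float(row["lat"]),
            age_min=float(row["age_min"]),
            age_max=float(row["age_max"]),
            map_id=str(row["map_id"]) if "map_id" in df.columns else None,
        ))
    return recs


def write_occurrences_csv(records: Iterable[OccurrenceRecord], path) -> None:
    pd.DataFrame([
        {
            "taxon": r.taxon, "locality_id": r.locality_id,
            "lon": r.lon, "lat": r.lat,
            "age_min": r.age_min, "age_max": r.age_max,
            "map_id": r.map_id,
        }
        for r in records
    ]).to_csv(path, index=False)


@dataclass
class Otu:
    label: str
    locality_ids: list[str]
    age_range: tuple[float, float]  # uniform tip-age prior (lo, hi)
    coding: str  # "ORIGINAL" or "ALL_MISSING"


@dataclass
class OtuExpansion:
    """Mapping original taxon -> OTUs plus the clade constraints implied by
    multi-OTU splits.  Exactly one OTU per taxon keeps the original coding
    and it carries the oldest age range."""

    mapping: dict[str, list[Otu]] = field(default_factory=dict)
    clade_constraints: list[set[str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for taxon, otus in self.mapping.items():
            for otu in otus:
                rows.append({
                    "taxon": taxon, "otu": otu.label,
                    "localities": ";".join(otu.locality_ids),
                    "age_lo": otu.age_range[0], "age_hi": otu.age_range[1],
                    "coding": otu.coding,
                })
        return pd.DataFrame(rows)


def _range_sort_key(rng: tuple[float, float], loc_ids: list[str]):
    # "oldest" = largest age_max, then largest age_min, then lowest id
    return (-rng[1], -rng[0], min(loc_ids))


def split_multilocality_otus(
    matrix: CharacterMatrix,
    occurrences: Sequence[OccurrenceRecord],
) -> tuple[CharacterMatrix, OtuExpansion]:
    """Split each taxon whose localities carry n distinct age ranges into n
    OTUs.  The OTU with the oldest range keeps the original character
    coding; younger OTUs are recoded all-missing (neutral), so morphological
    distances are forced onto earliest occurrences.  Each split taxon gets
    one clade constraint grouping its OTUs, and every OTU carries a uniform
    tip-age prior from its range."""
    by_taxon: dict[str, list[OccurrenceRecord]] = {}
    for rec in occurrences:
        by_taxon.setdefault(rec.taxon, []).append(rec)
    missing = [t for t in matrix.taxa if t not in by_taxon]
    if missing:
        raise ValueError(f"taxa with no occurrence: {missing}")

    expansion = OtuExpansion()
    new_taxa: list[str] = []
    new_rows: list[np.ndarray] = []
    for i, taxon in enumerate(matrix.taxa):
        groups: dict[tuple[float, float], list[str]] = {}
        for rec in by_taxon[taxon]:
            groups.setdefault((rec.age_min, rec.age_max), []).append(
                rec.locality_id
            )
        ranges = sorted(
            groups.items(), key=lambda kv: _range_sort_key(kv[0], kv[1])
        )
        otus = []
        for j, (rng, loc_ids) in enumerate(ranges):
            if len(ranges) == 1:
                label = taxon
            else:
                label = f"{taxon}_otu{j + 1}"
            coding = "ORIGINAL" if j == 0 else "ALL_MISSING"
            otus.append(Otu(label, sorted(loc_ids), rng, coding))
            new_taxa.append(label)
            if coding == "ORIGINAL":
                new_rows.append(matrix.data[i].copy())
            else:
                new_rows.append(np.full(matrix.n_char, MISSING, np.int16))
        expansion.mapping[taxon] = otus
        if len(otus) > 1:
            expansion.clade_constraints.append({o.label for o in otus})
    out = CharacterMatrix(
        new_taxa,
        np.vstack(new_rows) if new_rows else matrix.data[:0],
        matrix.ordered,
        matrix.partition,
        matrix.source,
    )
    return out, expansion


# ---------------------------------------------------------------------------
# Zone character
# ---------------------------------------------------------------------------


def zone_for_taxon(
    records: Sequence[OccurrenceRecord],
    scheme: Optional[ZoneScheme] = None,
    force_null: bool = False,
) -> Optional[int]:
    """Zone code for a taxon from its localities, or None ('?').

    A taxon is coded null when flagged (``force_null``, the wide-ranging
    Dugong rule), or when its localities straddle >= 3 zones or two
    non-adjacent zones.  Localities in two adjacent zones take the zone of
    the oldest occurrence."""
    if scheme is None:
        scheme = default_zone_scheme()
    if force_null or not records:
        return None
    zones = sorted({assign_zone(r.lon, scheme) for r in records})
    if len(zones) == 1:
        return zones[0]
    if len(zones) == 2 and scheme.adjacent(*zones):
        oldest = max(records, key=lambda r: (r.age_max, r.age_min))
        return assign_zone(oldest.lon, scheme)
    return None


def append_zone_character(
    matrix: CharacterMatrix,
    zone_map: dict[str, Optional[int]],
    scheme: Optional[ZoneScheme] = None,
) -> CharacterMatrix:
    """Append the ordered longitudinal-zone character as one extra column
    in its own partition.  Taxa mapped to None (unknown or deliberately
    nulled wide-rangers) get '?'."""
    if scheme is None:
        scheme = default_zone_scheme()
    codes = set(scheme.codes)
    col = np.full(matrix.n_taxa, MISSING, np.int16)
    for i, taxon in enumerate(matrix.taxa):
        z = zone_map.get(taxon)
        if z is None:
            continue
        if z not in codes:
            raise ValueError(f"zone {z} not in scheme")
        col[i] = z
    observed = set(col[col != MISSING].tolist())
    if len(observed) <= 1:
        warnings.warn(
            "zone character is invariant and would be dropped by variable "
            "coding", stacklevel=2,
        )
    new_pid = int(matrix.partition.max()) + 1 if matrix.n_char else 0
    return CharacterMatrix(
        matrix.taxa,
        np.hstack([matrix.data, col[:, None]]),
        np.append(matrix.ordered, True),
        np.append(matrix.partition, new_pid),
        list(matrix.source) + ["geographic_zone"],
    )


# ---------------------------------------------------------------------------
# Spherical centroid
# ---------------------------------------------------------------------------


def geocentroid(localities: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Spherical centroid of (lon, lat) points: mean of unit vectors,
    re-normalized, back to lon/lat.  Robust across the dateline (the naive
    arithmetic mean is not)."""
    if not localities:
        raise ValueError("geocentroid of empty set")
    xs = ys = zs = 0.0
    for lon, lat in localities:
        lam, phi = math.radians(lon), math.radians(lat)
        xs += math.cos(phi) * math.cos(lam)
        ys += math.cos(phi) * math.sin(lam)
        zs += math.sin(phi)
    n = len(localities)
    xs, ys, zs = xs / n, ys / n, zs / n
    norm = math.sqrt(xs * xs + ys * ys + zs * zs)
    if norm < 1e-12:
        raise ValueError("degenerate (antipodal) locality set: zero-norm mean")
    lat = math.degrees(math.asin(zs / norm))
    lon = math.degrees(math.atan2(ys, xs))
    if lon <= -180.0:
        lon += 360.0
    return lon, lat
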