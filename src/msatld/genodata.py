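"""Data model and I/O for multiallelic microsatellite genotypes and marker maps.

The central containers are :class:`GenotypeDataset` (per-population diploid
genotypes, allele codes are fragment sizes in base pairs) and
:class:`MarkerMap` (marker -> linkage group, physical position in Mb).
Genotypes are exchanged in the GenePop text format, the de-facto standard for
microsatellite data; marker maps and habitat tables are plain TSV.

Missing data follow the GenePop all-zeros convention.  A genotype with one
missing allele is treated as fully missing.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HABITATS = ("marine", "lake", "pond", "river")

MISSING = 0


class GenePopParseError(ValueError):
    """Raised when a GenePop file cannot be parsed; names the offending line."""


class ValidationError(ValueError):
    """Raised when inputs violate the data-model invariants."""


@dataclass
class Population:
    """Diploid genotypes of one sampled population.

    genotypes has shape (n_individuals, n_loci, 2), dtype int; allele codes
    are positive integers (fragment sizes in bp), 0 encodes missing.
    """

    name: str
    habitat: str
    coastal: bool
    genotypes: np.ndarray
    individual_names: list[str] = field(default_factory=list)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci); True where the genotype is missing."""
        return (self.genotypes == MISSING).any(axis=2)


@dataclass
class GenotypeDataset:
    """Multi-population diploid genotype table over a shared locus panel."""

    loci: list[str]
    populations: list[Population]
    motif_bp: np.ndarray | None = None  # per-locus repeat unit length

    def __post_init__(self) -> None:
        if self.motif_bp is None:
            self.motif_bp = np.full(len(self.loci), 4, dtype=int)
        else:
            self.motif_bp = np.asarray(self.motif_bp, dtype=int)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def population(self, name: str) -> Population:
        for pop in self.populations:
            if pop.name == name:
                return pop
        raise KeyError(f"population {name!r} not in dataset")

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise KeyError(f"locus {locus!r} not in dataset") from None

    def validate(self) -> None:
        for pop in self.populations:
            if pop.habitat not in HABITATS:
                raise ValidationError(
                    f"population {pop.name!r} has unknown habitat {pop.habitat!r}"
                )
            if pop.n_individuals < 1:
                raise ValidationError(f"population {pop.name!r} is empty")
            g = pop.genotypes
            if g.shape[1] != self.n_loci or g.shape[2] != 2:
                raise ValidationError(
                    f"population {pop.name!r}: genotype array shape {g.shape} "
                    f"inconsistent with {self.n_loci} loci"
                )
            if (g < 0).any():
                raise ValidationError(
                    f"population {pop.name!r}: negative allele codes"
                )

    def set_motifs_from_map(self, marker_map: "MarkerMap") -> None:
        """Attach per-locus motif lengths from the map's optional motif_bp column."""
        motifs = np.full(self.n_loci, 4, dtype=int)
        for i, locus in enumerate(self.loci):
            m = marker_map.motif_bp(locus)
            if m is not None:
                motifs[i] = m
        self.motif_bp = motifs


def normalize_missing(genotypes: np.ndarray) -> np.ndarray:
    """Set both alleles to 0 wherever either allele is 0 (half-missing rule)."""
    g = genotypes.copy()
    half = (g == MISSING).any(axis=-1)
    g[half] = MISSING
    return g


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------

class MarkerMap:
    """Physical marker map: marker id -> (linkage group, position in Mb).

    An optional ``motif_bp`` column carries per-marker repeat-unit lengths.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"marker", "lg", "position_mb"}
        missing_cols = required - set(table.columns)
        if missing_cols:
            raise ValidationError(f"marker map missing columns {sorted(missing_cols)}")
        if table["marker"].duplicated().any():
            dups = table.loc[table["marker"].duplicated(), "marker"].tolist()
            raise ValidationError(f"duplicate marker ids in map: {dups}")
        if (table["position_mb"] < 0).any():
            raise ValidationError("negative positions in marker map")
        self.table = table.reset_index(drop=True)
        self._by_marker = self.table.set_index("marker")

    @property
    def markers(self) -> list[str]:
        return self.table["marker"].tolist()

    def __contains__(self, marker: str) -> bool:
        return marker in self._by_marker.index

    def position(self, marker: str) -> float:
        return float(self._by_marker.at[marker, "position_mb"])

    def linkage_group(self, marker: str):
        return self._by_marker.at[marker, "lg"]

    def motif_bp(self, marker: str):
        if "motif_bp" not in self.table.columns or marker not in self:
            return None
        v = self._by_marker.at[marker, "motif_bp"]
        return None if pd.isna(v) else int(v)

    def syntenic_pairs(self, loci: list[str] | None = None) -> pd.DataFrame:
        """All unordered same-LG marker pairs, with |position difference| in Mb.

        Markers absent from ``loci`` (when given) are excluded; a dataset locus
        absent from the map is silently excluded from syntenic analyses.
        """
        tab = self.table
        if loci is not None:
            tab = tab[tab["marker"].isin(loci)]
        rows = []
        for lg, sub in tab.groupby("lg", sort=False):
            m = sub["marker"].to_numpy()
            pos = sub["position_mb"].to_numpy(dtype=float)
            order = np.argsort(pos, kind="stable")
            m, pos = m[order], pos[order]
            for i in range(len(m)):
                for j in range(i + 1, len(m)):
                    rows.append((m[i], m[j], lg, abs(pos[j] - pos[i])))
        return pd.DataFrame(rows, columns=["locusA", "locusB", "lg", "distance_mb"])

    def adjacent_interval_summary(self) -> dict:
        """Mean/median spacing between adjacent markers within linkage groups."""
        gaps = []
        for _, sub in self.table.groupby("lg", sort=False):
            pos = np.sort(sub["position_mb"].to_numpy(dtype=float))
            gaps.extend(np.diff(pos).tolist())
        gaps = np.asarray(gaps)
        return {
            "n_intervals": gaps.size,
            "mean_mb": float(gaps.mean()) if gaps.size else float("nan"),
            "median_mb": float(np.median(gaps)) if gaps.size else float("nan"),
        }


def read_marker_map(path) -> MarkerMap:
    table = pd.read_csv(path, sep="\t")
    return MarkerMap(table)


def write_marker_map(marker_map: MarkerMap, path) -> None:
    marker_map.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Habitat table
# ---------------------------------------------------------------------------

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def read_habitat_table(path) -> dict[str, tuple[str, bool]]:
    """TSV (population, habitat, coastal) -> {population: (habitat, coastal)}."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    required = {"population", "habitat", "coastal"}
    if not required <= set(tab.columns):
        raise ValidationError(f"habitat table must have columns {sorted(required)}")
    out: dict[str, tuple[str, bool]] = {}
    for _, row in tab.iterrows():
        habitat = row["habitat"].strip().lower()
        if habitat not in HABITATS:
            raise ValidationError(
                f"population {row['population']!r}: unknown habitat {habitat!r}"
            )
        flag = row["coastal"].strip().lower()
        if flag in _TRUE:
            coastal = True
        elif flag in _FALSE:
            coastal = False
        else:
            raise ValidationError(f"cannot parse coastal flag {row['coastal']!r}")
        out[row["population"]] = (habitat, coastal)
    return out


def write_habitat_table(dataset: GenotypeDataset, path) -> None:
    rows = [
        {"population": p.name, "habitat": p.habitat, "coastal": int(p.coastal)}
        for p in dataset.populations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GenePop I/O
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def read_genepop(path, habitat_table) -> GenotypeDataset:
    """Read a GenePop file (4- or 6-digit dialect, auto-detected).

    ``habitat_table`` is a path to a habitat TSV or an already-parsed mapping
    ``{population: (habitat, coastal)}``.  Each population is named after its
    first individual's label (a common GenePop idiom); every population in the
    file must appear in the habitat table.
    """
    if not isinstance(habitat_table, dict):
        habitat_table = read_habitat_table(habitat_table)

    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    if not lines:
        raise GenePopParseError("empty GenePop file")

    # Header: title line, then locus names until the first POP line.
    loci: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if i == len(lines):
        raise GenePopParseError("no POP line found")
    if not loci:
        raise GenePopParseError("no locus names before first POP line")

    pops_raw: list[list[tuple[str, list[str], int]]] = []
    current: list[tuple[str, list[str], int]] | None = None
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if _POP_RE.match(line):
            current = []
            pops_raw.append(current)
            continue
        if not line.strip():
            continue
        if "," not in line:
            raise GenePopParseError(
                f"line {lineno + 1}: expected 'name , genotypes...'"
            )
        name, _, rest = line.partition(",")
        tokens = rest.split()
        if len(tokens) != len(loci):
            raise GenePopParseError(
                f"line {lineno + 1}: {len(tokens)} genotype fields for "
                f"{len(loci)} loci"
            )
        current.append((name.strip(), tokens, lineno + 1))

    # Dialect detection: 4 digits (2 per allele) or 6 digits (3 per allele).
    widths = {len(t) for pop in pops_raw for _, tokens, _ in pop for t in tokens}
    if widths <= {4}:
        half = 2
    elif widths <= {6}:
        half = 3
    else:
        raise GenePopParseError(
            f"inconsistent genotype field widths {sorted(widths)}; "
            "expected all 4-digit or all 6-digit"
        )

    populations = []
    for pop_raw in pops_raw:
        if not pop_raw:
            raise GenePopParseError("empty population block")
        pop_name = pop_raw[0][0]
        if pop_name not in habitat_table:
            raise ValidationError(
                f"population {pop_name!r} missing from habitat table"
            )
        geno = np.zeros((len(pop_raw), len(loci), 2), dtype=np.int32)
        ind_names = []
        for k, (ind, tokens, lineno) in enumerate(pop_raw):
            ind_names.append(ind if k == 0 else f"{pop_name}_{k}")
            for l, tok in enumerate(tokens):
                if not tok.isdigit():
                    raise GenePopParseError(
                        f"line {lineno}: malformed allele field {tok!r}"
                    )
                geno[k, l, 0] = int(tok[:half])
                geno[k, l, 1] = int(tok[half:])
        habitat, coastal = habitat_table[pop_name]
        populations.append(
            Population(pop_name, habitat, coastal, normalize_missing(geno), ind_names)
        )

    dataset = GenotypeDataset(loci=loci, populations=populations)
    dataset.validate()
    return dataset


def write_genepop(dataset: GenotypeDataset, path, title: str = "msatld export") -> None:
    """Write GenePop text; 6-digit dialect if any allele code exceeds 99."""
    max_code = max(
        (int(p.genotypes.max()) for p in dataset.populations), default=0
    )
    half = 3 if max_code > 99 else 2
    if max_code >= 10 ** half:
        raise ValidationError(
            f"allele code {max_code} does not fit the {2 * half}-digit dialect"
        )
    buf = io.StringIO()
    buf.write(title + "\n")
    for locus in dataset.loci:
        buf.write(locus + "\n")
    for pop in dataset.populations:
        buf.write("POP\n")
        for ind in range(pop.n_individuals):
            fields = [
                f"{a:0{half}d}{b:0{half}d}" for a, b in pop.genotypes[ind]
            ]
            buf.write(f"{pop.name} , " + " ".join(fields) + "\n")
    text = buf.getvalue()
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

class AlleleFrequencyTable:
    """Per-population, per-locus allele relative frequencies.

    ``get(pop, locus)`` returns ``(alleles, freqs, gene_count)`` where
    ``gene_count`` is twice the number of non-missing individuals.  A locus
    with zero non-missing copies in a population is flagged *absent*.
    """

    def __init__(self):
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, int]] = {}

    def set(self, pop: str, locus: str, alleles, freqs, gene_count: int) -> None:
        self._data[(pop, locus)] = (
            np.asarray(alleles),
            np.asarray(freqs, dtype=float),
            int(gene_count),
        )

    def get(self, pop: str, locus: str):
        return self._data[(pop, locus)]

    def is_absent(self, pop: str, locus: str) -> bool:
        if (pop, locus) not in self._data:
            return True
        return self._data[(pop, locus)][2] == 0

    def items(self):
        return self._data.items()


def allele_counts(pop: Population, locus_idx: int) -> tuple[np.ndarray, np.ndarray]:
    """Observed alleles and their copy counts at one locus (missing excluded)."""
    copies = pop.genotypes[:, locus_idx, :].ravel()
    copies = copies[copies != MISSING]
    return np.unique(copies, return_counts=True)


def allele_frequencies(dataset: GenotypeDataset) -> AlleleFrequencyTable:
    table = AlleleFrequencyTable()
    for pop in dataset.populations:
        for l, locus in enumerate(dataset.loci):
            alleles, counts = allele_counts(pop, l)
            total = int(counts.sum())
            if total == 0:
                table.set(pop.name, locus, np.array([], dtype=int), np.array([]), 0)
            else:
                table.set(pop.name, locus, alleles, counts / total, total)
    return table
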