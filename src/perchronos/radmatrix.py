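"""RAD locus matrices: I/O, coverage filtering, concatenation, site statistics
and uncorrected P distances.

The data model mirrors a typical ddRAD phylogenomic matrix: thousands of short
(~80 bp) loci scored over a few dozen diploid individuals, with heterozygous
sites encoded as two-base IUPAC ambiguity codes and whole loci missing for
individuals that dropped out during assembly.  Loci are kept as units through
filtering; a locus either passes the coverage threshold or is discarded whole.

Conventions (documented choices, applied consistently downstream):

* The gap character ``-`` and ``N`` are missing data, never character states.
* Two-base ambiguity codes (R, Y, S, W, K, M) are real observations of a
  heterozygous genotype, but are excluded from SNP/PIS counts and from
  P-distance comparisons (pairwise deletion), since those statistics are
  defined on unambiguous bases.
* P distances use pairwise deletion: each pair of individuals is compared
  over the sites where *both* carry an unambiguous base.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = set("ACGTRYSWKMN-")
#: IUPAC two-base (heterozygote) codes
HET_CODES = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC"}
MISSING = "N"
GAP = "-"

_BASES = b"ACGT"
# byte value -> 0..3 for unambiguous bases, -1 otherwise
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[_b] = _i
# missing cells for the missing-data percentage: N and gap
_IS_MISSING = np.zeros(256, dtype=bool)
_IS_MISSING[ord("N")] = True
_IS_MISSING[ord("-")] = True


class RadMatrixError(ValueError):
    """Base class for locus-matrix errors."""


class MalformedHeaderError(RadMatrixError):
    """FASTA header does not follow '>individualID locusID'."""


class LocusLengthError(RadMatrixError):
    """Sequences within one locus differ in length."""


class AlphabetError(RadMatrixError):
    """Sequence contains a character outside the IUPAC alphabet."""


class MetadataMismatchError(RadMatrixError):
    """Metadata table does not cover every individual in the matrix."""


class UndefinedDistanceError(RadMatrixError):
    """A pair of individuals shares no comparable site."""


@dataclass(frozen=True)
class IndividualInfo:
    population: str
    species: str
    region: str  # 'E' or 'W'


@dataclass
class Locus:
    locus_id: str
    length: int
    sequences: dict[str, str]  # individual id -> aligned sequence

    def coverage(self) -> int:
        return len(self.sequences)

    def validate(self) -> None:
        for ind, seq in self.sequences.items():
            if len(seq) != self.length:
                raise LocusLengthError(
                    f"locus {self.locus_id}: sequence for {ind} has length "
                    f"{len(seq)}, expected {self.length}"
                )
            bad = set(seq) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"locus {self.locus_id}: individual {ind} carries "
                    f"characters outside the IUPAC alphabet: {sorted(bad)}"
                )


@dataclass
class LocusMatrix:
    loci: list[Locus]
    individuals: list[str]
    metadata: dict[str, IndividualInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            raise RadMatrixError("individual ids are not unique")
        for locus in self.loci:
            locus.validate()
            unknown = set(locus.sequences) - set(self.individuals)
            if unknown:
                raise MetadataMismatchError(
                    f"locus {locus.locus_id} has sequences for unlisted "
                    f"individuals: {sorted(unknown)}"
                )
        if self.metadata:
            uncovered = set(self.individuals) - set(self.metadata)
            if uncovered:
                raise MetadataMismatchError(
                    f"metadata missing for individuals: {sorted(uncovered)}"
                )

    def n_loci(self) -> int:
        return len(self.loci)

    def coverage_table(self) -> pd.Series:
        return pd.Series(
            {loc.locus_id: loc.coverage() for loc in self.loci}, dtype=int
        )


@dataclass
class ConcatenatedAlignment:
    individuals: list[str]
    matrix: np.ndarray  # (n_individuals, n_sites), dtype 'S1'
    partitions: dict[str, tuple[int, int]]  # locus -> [start, end)
    metadata: dict[str, IndividualInfo] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    def row(self, individual: str) -> str:
        i = self.individuals.index(individual)
        return self.matrix[i].tobytes().decode("ascii")

    def subset(self, individuals: list[str]) -> "ConcatenatedAlignment":
        idx = [self.individuals.index(i) for i in individuals]
        return ConcatenatedAlignment(
            list(individuals),
            self.matrix[idx],
            dict(self.partitions),
            {i: self.metadata[i] for i in individuals if i in self.metadata},
        )


@dataclass
class SiteStats:
    n_snps: int
    n_pis: int
    missing_pct: float
    n_sites: int
    n_individuals: int


@dataclass
class DistanceMatrix:
    individuals: list[str]
    values: np.ndarray  # square, symmetric, NaN where undefined
    undefined_pairs: list[tuple[str, str]] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individuals, columns=self.individuals
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_locus_fasta(path, metadata: dict[str, IndividualInfo] | None = None,
                     individuals: list[str] | None = None) -> LocusMatrix:
    """Read a multi-locus FASTA with headers ``>individualID locusID``.

    Loci appear in order of first appearance; ``individuals`` fixes the row
    order (defaults to order of first appearance).
    """
    loci: dict[str, Locus] = {}
    seen_individuals: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()
        if len(parts) < 2:
            raise MalformedHeaderError(
                f"header '{rec.description}' lacks the locus id "
                "(expected '>individualID locusID')"
            )
        ind, locus_id = parts[0], parts[1]
        seq = str(rec.seq).upper()
        if ind not in seen_individuals:
            seen_individuals.append(ind)
        if locus_id not in loci:
            loci[locus_id] = Locus(locus_id, len(seq), {})
        loci[locus_id].sequences[ind] = seq
    if individuals is None:
        individuals = seen_individuals
    if metadata is not None:
        missing = set(individuals) - set(metadata)
        if missing:
            raise MetadataMismatchError(
                f"metadata missing for individuals: {sorted(missing)}"
            )
    return LocusMatrix(list(loci.values()), list(individuals), metadata or {})


def write_locus_fasta(m: LocusMatrix, path) -> None:
    records = []
    for locus in m.loci:
        for ind in m.individuals:
            if ind in locus.sequences:
                records.append(
                    SeqRecord(Seq(locus.sequences[ind]), id=ind,
                              description=f"{ind} {locus.locus_id}")
                )
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} {rec.description.split()[1]}\n{rec.seq}\n")


def write_phylip(a: ConcatenatedAlignment, phylip_path, partition_path=None) -> None:
    """Write relaxed PHYLIP plus a TSV partition table (0-based half-open)."""
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(a.row(ind)), id=ind, description="")
        for ind in a.individuals
    )
    with open(phylip_path, "w") as fh:
        AlignIO.write(msa, fh, "phylip-relaxed")
    if partition_path is not None:
        rows = [{"locus": k, "start": s, "end": e}
                for k, (s, e) in a.partitions.items()]
        pd.DataFrame(rows).to_csv(partition_path, sep="\t", index=False)


def read_phylip(phylip_path, partition_path,
                metadata: dict[str, IndividualInfo] | None = None) -> LocusMatrix:
    """Read a concatenated PHYLIP + partition table back into a LocusMatrix.

    A locus is recorded as absent for an individual when its slice is
    entirely missing symbols (all ``N``/``-``).
    """
    with open(phylip_path) as fh:
        msa = AlignIO.read(fh, "phylip-relaxed")
    parts = pd.read_csv(partition_path, sep="\t")
    individuals = [rec.id for rec in msa]
    rows = {rec.id: str(rec.seq).upper() for rec in msa}
    loci = []
    for _, p in parts.iterrows():
        start, end = int(p["start"]), int(p["end"])
        seqs = {}
        for ind in individuals:
            chunk = rows[ind][start:end]
            if set(chunk) <= {MISSING, GAP} and MISSING in set(chunk):
                continue  # treated as absent locus
            seqs[ind] = chunk
        loci.append(Locus(str(p["locus"]), end - start, seqs))
    m = LocusMatrix(loci, individuals, metadata or {})
    for locus in m.loci:
        locus.validate()
    return m


# ---------------------------------------------------------------------------
# Filtering & concatenation
# ---------------------------------------------------------------------------

def filter_by_coverage(m: LocusMatrix, min_individuals: int) -> LocusMatrix:
    """Retain loci scored in at least ``min_individuals`` individuals."""
    if not 0 <= min_individuals <= len(m.individuals):
        raise ValueError(
            f"min_individuals must be in [0, {len(m.individuals)}]"
        )
    kept = [loc for loc in m.loci if loc.coverage() >= min_individuals]
    return LocusMatrix(kept, list(m.individuals), dict(m.metadata))


def coverage_threshold_pct(min_individuals: int, n_individuals: int) -> float:
    """Coverage threshold as a percentage of individuals (e.g. 40/45 -> 88.9)."""
    return 100.0 * min_individuals / n_individuals


def concatenate(m: LocusMatrix) -> ConcatenatedAlignment:
    """Concatenate loci into one supermatrix, filling absent loci with N."""
    if not m.loci:
        raise RadMatrixError("cannot concatenate an empty locus matrix")
    total = sum(loc.length for loc in m.loci)
    n = len(m.individuals)
    mat = np.full((n, total), MISSING.encode(), dtype="S1")
    partitions: dict[str, tuple[int, int]] = {}
    pos = 0
    ind_idx = {ind: i for i, ind in enumerate(m.individuals)}
    for locus in m.loci:
        end = pos + locus.length
        partitions[locus.locus_id] = (pos, end)
        for ind, seq in locus.sequences.items():
            mat[ind_idx[ind], pos:end] = np.frombuffer(
                seq.encode("ascii"), dtype="S1"
            )
        pos = end
    return ConcatenatedAlignment(list(m.individuals), mat, partitions,
                                 dict(m.metadata))


# ---------------------------------------------------------------------------
# Site statistics & distances
# ---------------------------------------------------------------------------

def site_stats(a: ConcatenatedAlignment,
               subset: list[str] | None = None) -> SiteStats:
    """SNP / parsimony-informative-site counts and missing-data percentage.

    A SNP is a site with >= 2 distinct unambiguous bases among the subset's
    non-missing, non-ambiguous characters; a PIS additionally requires >= 2
    of those states each carried by >= 2 individuals.  Missing cells are
    ``N`` and ``-``.
    """
    if subset is None:
        subset = list(a.individuals)
    if not subset:
        raise ValueError("subset is empty")
    idx = [a.individuals.index(i) for i in subset]
    sub = a.matrix[idx].view(np.uint8)
    codes = _CODE[sub]  # (n, L), -1 for non-ACGT
    counts = np.stack([(codes == b).sum(axis=0) for b in range(4)])  # (4, L)
    n_states = (counts > 0).sum(axis=0)
    n_snps = int((n_states >= 2).sum())
    n_pis = int(((counts >= 2).sum(axis=0) >= 2).sum())
    missing = _IS_MISSING[sub].sum()
    missing_pct = 100.0 * missing / sub.size
    return SiteStats(n_snps, n_pis, float(missing_pct), a.n_sites, len(subset))


def p_distance_matrix(a: ConcatenatedAlignment) -> DistanceMatrix:
    """Pairwise uncorrected P distances with pairwise deletion.

    Comparable sites are those where both individuals carry an unambiguous
    base (A/C/G/T).  Pairs with zero comparable sites get NaN and are listed
    in ``undefined_pairs``.
    """
    n = a.n_individuals
    if n < 2:
        raise RadMatrixError("need >= 2 individuals for a distance matrix")
    codes = _CODE[a.matrix.view(np.uint8)]
    valid = codes >= 0
    d = np.zeros((n, n))
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comp = int(both.sum())
            if comp == 0:
                d[i, j] = d[j, i] = np.nan
                undefined.append((a.individuals[i], a.individuals[j]))
            else:
                mism = int((codes[i][both] != codes[j][both]).sum())
                d[i, j] = d[j, i] = mism / comp
    return DistanceMatrix(list(a.individuals), d, undefined)


def group_mean_distances(d: DistanceMatrix,
                         grouping: dict[str, str]) -> pd.DataFrame:
    """Within/between-group mean P distances, reported in percent.

    Within-group means average over unordered pairs inside the group
    (NaN for singleton groups); between-group means average over all cross
    pairs.  Returned as a square DataFrame over group labels.
    """
    missing = set(d.individuals) - set(grouping)
    if missing:
        raise ValueError(f"unlabelled individuals: {sorted(missing)}")
    labels = sorted({grouping[i] for i in d.individuals})
    members = {g: [k for k, ind in enumerate(d.individuals)
                   if grouping[ind] == g] for g in labels}
    out = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for gi, g in enumerate(labels):
        for h in labels[gi:]:
            if g == h:
                idx = members[g]
                if len(idx) < 2:
                    continue  # singleton: within-group mean undefined
                vals = [d.values[i, j] for ii, i in enumerate(idx)
                        for j in idx[ii + 1:]]
            else:
                vals = [d.values[i, j] for i in members[g]
                        for j in members[h]]
            mean = 100.0 * float(np.mean(vals))
            out.loc[g, h] = mean
            out.loc[h, g] = mean
    return out


# ---------------------------------------------------------------------------
# Table-2-style summary
# ---------------------------------------------------------------------------

def dataset_summary(m: LocusMatrix, a: ConcatenatedAlignment,
                    outgroup_species: set[str] | None = None) -> pd.DataFrame:
    """Locus/SNP/PIS/missing summary for all individuals, ingroup, outgroup."""
    rows = []
    subsets = {"all individuals": list(a.individuals)}
    if outgroup_species and m.metadata:
        ingroup = [i for i in a.individuals
                   if m.metadata[i].species not in outgroup_species]
        outgroup = [i for i in a.individuals
                    if m.metadata[i].species in outgroup_species]
        if ingroup:
            subsets["ingroup only"] = ingroup
        if outgroup:
            subsets["outgroup only"] = outgroup
    for name, subset in subsets.items():
        st = site_stats(a, subset)
        mean_loci = float(np.mean(
            [sum(1 for loc in m.loci if ind in loc.sequences)
             for ind in subset]
        ))
        rows.append({
            "subset": name,
            "sequence_length_bp": a.n_sites,
            "n_loci": m.n_loci(),
            "n_snps": st.n_snps,
            "n_pis": st.n_pis,
            "mean_loci_per_individual": mean_loci,
            "missing_pct": st.missing_pct,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Packaged locality fixture (study metadata table)
# ---------------------------------------------------------------------------

def load_locality_table() -> pd.DataFrame:
    """Sampling localities: species, location, population abbreviation, n, region."""
    from importlib.resources import files

    src = files("perchronos").joinpath("data/table1_localities.tsv")
    return pd.read_csv(io.StringIO(src.read_text()), sep="\t")


def locality_metadata(table: pd.DataFrame | None = None) -> dict[str, IndividualInfo]:
    """Expand the locality table into per-individual metadata (ids ABBR1, ABBR2...)."""
    if table is None:
        table = load_locality_table()
    meta: dict[str, IndividualInfo] = {}
    for _, row in table.iterrows():
        for k in range(1, int(row["n"]) + 1):
            meta[f"{row['abbreviation']}{k}"] = IndividualInfo(
                population=row["abbreviation"],
                species=row["species"],
                region=row["region"],
            )
    return meta
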