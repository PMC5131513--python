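"""Data model and readers/writers for codominant genotypes and derived objects.

The central container is :class:`GenotypeDataset`: diploid multilocus
genotypes at codominant markers (microsatellites/SSRs and biallelic SNPs),
with per-locus marker metadata.  Alongside it live the cluster-membership
matrix (``q`` coefficients from Bayesian clustering runs), hard cluster
assignments at a threshold, phased haplotype pairs for a nuclear gene, and
labelled symmetric distance matrices.

File formats
------------
* Genotype CSV ("csv-pairs" dialect): one row per individual, columns
  ``ind,pop,<locus1>,<locus2>,...`` where each locus cell is ``a/b`` and
  missing data is ``-/-``.  Marker metadata travels in comment lines::

      # locus ssr1 SSR motif=3
      # locus snp1 SNP

  SSR alleles may be given either as repeat counts (``motif=1``) or as
  fragment sizes in bp, which are converted to repeat counts by dividing by
  the motif length and rounding half-up.
* GENEPOP (read-only, 2- or 3-digit allele coding).
* Phased FASTA with headers ``INDID|1`` and ``INDID|2``.
* Labelled square CSV for distance matrices.

All writers emit UTF-8 with ``#``-prefixed header comment lines.
"""

from __future__ import annotations

import csv
import io
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ValidationError",
    "UNDEFINED",
    "SSR",
    "SNP",
    "Locus",
    "GenotypeDataset",
    "MembershipMatrix",
    "ClusterAssignment",
    "PhasedHaplotypeSet",
    "LabeledDistanceMatrix",
    "read_genotype_table",
    "write_genotype_table",
    "summarize_alleles",
    "read_membership_matrix",
    "write_membership_matrix",
    "read_phased_fasta",
    "write_phased_fasta",
    "read_distance_csv",
    "write_distance_csv",
]


class FormatError(ValueError):
    """Raised when an input file does not conform to its dialect."""


class ValidationError(ValueError):
    """Raised when parsed data violate a container invariant."""


#: Sentinel label for individuals not assigned to any cluster (max q <= threshold).
UNDEFINED = "UNDEFINED"

SSR = "SSR"
SNP = "SNP"

_HAP_ALPHABET = frozenset("ACGT-")


@dataclass(frozen=True)
class Locus:
    """A codominant marker locus.

    ``motif_length`` is the repeat-motif length in bp for SSRs (1 means the
    allele codes already are repeat counts); it is ignored for SNPs.
    """

    name: str
    marker_type: str
    motif_length: int = 1

    def __post_init__(self) -> None:
        if self.marker_type not in (SSR, SNP):
            raise ValidationError(
                f"locus {self.name!r}: marker_type must be 'SSR' or 'SNP', "
                f"got {self.marker_type!r}"
            )
        if self.motif_length < 1:
            raise ValidationError(f"locus {self.name!r}: motif_length must be >= 1")


Call = Optional[tuple[int, int]]


@dataclass
class GenotypeDataset:
    """Diploid multilocus genotypes with marker-type metadata.

    ``calls[i][l]`` is the unordered allele pair of individual ``i`` at locus
    ``l``, stored as ``(min, max)``, or ``None`` if fully missing.  Half
    calls are not representable: a call is either complete or missing.
    """

    individuals: list[str]
    loci: list[Locus]
    calls: list[list[Call]]
    group_labels: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            raise ValidationError("individual IDs are not unique")
        if len(self.calls) != len(self.individuals):
            raise ValidationError("calls do not match the individual list")
        n_loci = len(self.loci)
        for ind, row in zip(self.individuals, self.calls):
            if len(row) != n_loci:
                raise ValidationError(f"individual {ind!r}: wrong number of loci")
        for l, locus in enumerate(self.loci):
            observed = self.observed_alleles(l)
            if locus.marker_type == SNP and len(observed) > 2:
                raise ValidationError(
                    f"SNP locus {locus.name!r} shows {len(observed)} alleles "
                    f"({sorted(observed)}); at most 2 allowed"
                )
            if locus.marker_type == SSR and any(a < 1 for a in observed):
                raise ValidationError(
                    f"SSR locus {locus.name!r}: allele codes must be positive "
                    "repeat counts"
                )

    # -- accessors -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_indices(self, marker_type: Optional[str] = None) -> list[int]:
        return [
            l
            for l, locus in enumerate(self.loci)
            if marker_type is None or locus.marker_type == marker_type
        ]

    def observed_alleles(self, locus_index: int) -> set[int]:
        out: set[int] = set()
        for row in self.calls:
            call = row[locus_index]
            if call is not None:
                out.update(call)
        return out

    def allele_counts(
        self, locus_index: int, individuals: Optional[Iterable[str]] = None
    ) -> Counter:
        """Gene-copy counts per allele, with pairwise deletion of missing calls."""
        if individuals is None:
            rows = range(self.n_individuals)
        else:
            pos = {ind: i for i, ind in enumerate(self.individuals)}
            rows = [pos[ind] for ind in individuals]
        counts: Counter = Counter()
        for i in rows:
            call = self.calls[i][locus_index]
            if call is not None:
                counts[call[0]] += 1
                counts[call[1]] += 1
        return counts

    def subset(
        self,
        individuals: Optional[Sequence[str]] = None,
        locus_indices: Optional[Sequence[int]] = None,
    ) -> "GenotypeDataset":
        inds = list(individuals) if individuals is not None else list(self.individuals)
        locs = list(locus_indices) if locus_indices is not None else list(range(self.n_loci))
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        calls = [[self.calls[pos[ind]][l] for l in locs] for ind in inds]
        labels = None
        if self.group_labels is not None:
            labels = {ind: self.group_labels[ind] for ind in inds if ind in self.group_labels}
        return GenotypeDataset(inds, [self.loci[l] for l in locs], calls, labels)

    def merge_loci(self, other: "GenotypeDataset") -> "GenotypeDataset":
        """Concatenate the loci of two datasets over the same individuals."""
        if self.individuals != other.individuals:
            raise ValidationError("cannot merge: individual lists differ")
        calls = [a + b for a, b in zip(self.calls, other.calls)]
        return GenotypeDataset(
            list(self.individuals),
            self.loci + other.loci,
            calls,
            dict(self.group_labels) if self.group_labels else None,
        )


@dataclass
class MembershipMatrix:
    """Per-individual cluster membership coefficients from one clustering run."""

    run_id: str
    individuals: list[str]
    q: np.ndarray  # shape (n_individuals, K)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2 or self.q.shape[0] != len(self.individuals):
            raise ValidationError("q must be (n_individuals, K)")
        if np.any(self.q < -1e-12) or np.any(self.q > 1 + 1e-12):
            raise ValidationError("q coefficients must lie in [0, 1]")
        rows = self.q.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValidationError("q rows must sum to 1 within 1e-9")

    @property
    def K(self) -> int:
        return self.q.shape[1]


@dataclass
class ClusterAssignment:
    """Hard cluster calls: a label where max q exceeds the threshold, else UNDEFINED."""

    assignments: dict[str, str]
    threshold: float

    @property
    def individuals(self) -> list[str]:
        return list(self.assignments)

    def defined(self) -> dict[str, str]:
        return {i: c for i, c in self.assignments.items() if c != UNDEFINED}

    def cluster_sizes(self) -> Counter:
        return Counter(self.assignments.values())


@dataclass
class PhasedHaplotypeSet:
    """Exactly two aligned haplotype sequences per individual.

    Sequences are over ``{A, C, G, T, -}``; the gap character is a legitimate
    fifth state (alignment-induced length variants), not missing data.
    """

    individuals: list[str]
    sequences: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if set(self.individuals) != set(self.sequences):
            raise ValidationError("individual list and sequence map disagree")
        lengths = {len(s) for pair in self.sequences.values() for s in pair}
        if len(lengths) > 1:
            raise ValidationError(f"aligned lengths differ: {sorted(lengths)}")
        for ind, pair in self.sequences.items():
            if len(pair) != 2:
                raise ValidationError(f"individual {ind!r} has {len(pair)} haplotypes")
            for s in pair:
                bad = set(s) - _HAP_ALPHABET
                if bad:
                    raise ValidationError(
                        f"individual {ind!r}: invalid characters {sorted(bad)}"
                    )

    @property
    def alignment_length(self) -> int:
        first = next(iter(self.sequences.values()))
        return len(first[0])

    def haplotype_multiplicities(self) -> Counter:
        """Distinct sequences with their copy numbers (sums to 2 x n_individuals)."""
        counts: Counter = Counter()
        for ind in self.individuals:
            a, b = self.sequences[ind]
            counts[a] += 1
            counts[b] += 1
        return counts


_METRICS_ZERO_DIAG = {"FST", "DS", "DELTA_MU_SQ"}
_METRICS_NONNEG = {"FST", "DELTA_MU_SQ"}


@dataclass
class LabeledDistanceMatrix:
    """Square symmetric matrix of pairwise cluster distances (or overlaps)."""

    labels: list[str]
    values: np.ndarray
    metric_name: str = "custom"
    global_value: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValidationError("labels are not unique")
        with np.errstate(invalid="ignore"):
            # exact equality also covers +inf entries (no shared alleles)
            mismatch = ~(
                (self.values == self.values.T)
                | (np.abs(self.values - self.values.T) <= 1e-12)
            )
        if np.any(mismatch):
            raise ValidationError("matrix is not symmetric within 1e-12")
        diag = np.diag(self.values)
        expected_diag = 1.0 if self.metric_name == "NICHE_D" else 0.0
        if self.metric_name in _METRICS_ZERO_DIAG or self.metric_name == "NICHE_D":
            if np.any(np.abs(diag - expected_diag) > 1e-12):
                raise ValidationError(
                    f"{self.metric_name}: diagonal must equal {expected_diag}"
                )
        if self.metric_name in _METRICS_NONNEG and np.any(self.values < -1e-12):
            raise ValidationError(f"{self.metric_name} values must be non-negative")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def condensed(self) -> np.ndarray:
        """Upper-triangle off-diagonal values, row-major (label order)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def pair_labels(self) -> list[tuple[str, str]]:
        n = len(self.labels)
        return [(self.labels[i], self.labels[j]) for i in range(n) for j in range(i + 1, n)]

    def reordered(self, labels: Sequence[str]) -> "LabeledDistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return LabeledDistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.metric_name, self.global_value
        )


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

_LOCUS_COMMENT = re.compile(
    r"^#\s*locus\s+(?P<name>\S+)\s+(?P<type>SSR|SNP)(?:\s+motif=(?P<motif>\d+))?\s*$"
)


def _convert_ssr(value: int, motif_length: int) -> int:
    """bp fragment size -> repeat count, rounding half-up."""
    if motif_length == 1:
        return value
    return math.floor(value / motif_length + 0.5)


def _parse_call(token: str, locus: Locus, where: str) -> Call:
    token = token.strip()
    parts = token.split("/")
    if len(parts) != 2:
        raise FormatError(f"{where}: malformed call {token!r} (expected 'a/b')")
    if parts[0] == "-" and parts[1] == "-":
        return None
    if "-" in parts:
        raise FormatError(f"{where}: half-missing call {token!r} not allowed")
    try:
        a, b = (int(p) for p in parts)
    except ValueError as exc:
        raise FormatError(f"{where}: non-integer allele in {token!r}") from exc
    if locus.marker_type == SSR:
        a = _convert_ssr(a, locus.motif_length)
        b = _convert_ssr(b, locus.motif_length)
    return (min(a, b), max(a, b))


def read_genotype_table(path: str | Path, dialect: str = "csv-pairs") -> GenotypeDataset:
    """Read a genotype table in the ``csv-pairs`` or ``genepop`` dialect."""
    path = Path(path)
    if dialect == "csv-pairs":
        return _read_csv_pairs(path)
    if dialect == "genepop":
        return _read_genepop(path)
    raise FormatError(f"unknown dialect {dialect!r}")


def _read_csv_pairs(path: Path) -> GenotypeDataset:
    meta: dict[str, tuple[str, int]] = {}
    data_lines: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = _LOCUS_COMMENT.match(line)
                if m:
                    motif = int(m.group("motif") or 1)
                    meta[m.group("name")] = (m.group("type"), motif)
                continue
            data_lines.append(line)
    if not data_lines:
        raise FormatError(f"{path}: no data rows")
    reader = csv.reader(io.StringIO("\n".join(data_lines)))
    header = next(reader)
    if len(header) < 3 or header[0].lower() != "ind" or header[1].lower() != "pop":
        raise FormatError(f"{path}: header must start with 'ind,pop,<loci...>'")
    loci = []
    for name in header[2:]:
        mtype, motif = meta.get(name, (SSR, 1))
        loci.append(Locus(name, mtype, motif))
    individuals: list[str] = []
    calls: list[list[Call]] = []
    groups: dict[str, str] = {}
    for ln, row in enumerate(reader, start=2):
        if len(row) != len(header):
            raise FormatError(f"{path} line {ln}: expected {len(header)} fields")
        ind = row[0].strip()
        individuals.append(ind)
        if row[1].strip():
            groups[ind] = row[1].strip()
        calls.append(
            [
                _parse_call(tok, loc, f"{path} line {ln} locus {loc.name}")
                for tok, loc in zip(row[2:], loci)
            ]
        )
    return GenotypeDataset(individuals, loci, calls, groups or None)


def write_genotype_table(g: GenotypeDataset, path: str | Path) -> None:
    """Write the ``csv-pairs`` dialect; repeat counts are emitted as-is (motif=1)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# cryptodelim genotype table (csv-pairs dialect)\n")
        for locus in g.loci:
            # emitted codes are already repeat counts, so motif is recorded as 1
            fh.write(f"# locus {locus.name} {locus.marker_type} motif=1\n")
        writer = csv.writer(fh)
        writer.writerow(["ind", "pop"] + [l.name for l in g.loci])
        for ind, row in zip(g.individuals, g.calls):
            pop = (g.group_labels or {}).get(ind, "")
            cells = ["-/-" if c is None else f"{c[0]}/{c[1]}" for c in row]
            writer.writerow([ind, pop] + cells)


def _read_genepop(path: Path) -> GenotypeDataset:
    """GENEPOP reader (2- or 3-digit coding).  All loci are treated as SSRs
    with motif 1 since the format carries no marker metadata."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated GENEPOP file")
    body = lines[1:]  # first line is the title
    locus_names: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        locus_names.extend(n.strip() for n in body[i].split(",") if n.strip())
        i += 1
    if i == len(body):
        raise FormatError(f"{path}: no POP section")
    loci = [Locus(name, SSR, 1) for name in locus_names]
    individuals: list[str] = []
    calls: list[list[Call]] = []
    groups: dict[str, str] = {}
    pop_index = 0
    for line in body[i:]:
        if line.strip().upper() == "POP":
            pop_index += 1
            continue
        if "," not in line:
            raise FormatError(f"{path}: malformed sample line {line!r}")
        ind, geno = line.split(",", 1)
        ind = ind.strip()
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise FormatError(
                f"{path}: individual {ind!r} has {len(tokens)} genotypes, "
                f"expected {len(loci)}"
            )
        row: list[Call] = []
        for tok, locus in zip(tokens, loci):
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise FormatError(
                    f"{path}: individual {ind!r} locus {locus.name}: bad token {tok!r}"
                )
            w = len(tok) // 2
            a, b = int(tok[:w]), int(tok[w:])
            row.append(None if a == 0 or b == 0 else (min(a, b), max(a, b)))
        individuals.append(ind)
        groups[ind] = f"pop{pop_index}"
        calls.append(row)
    return GenotypeDataset(individuals, loci, calls, groups)


def summarize_alleles(g: GenotypeDataset) -> dict:
    """Per-marker-type allele totals and the SNP/SSR allele ratio.

    ``n_alleles`` counts distinct observed allele codes summed over loci;
    ``alleles_minus_loci`` subtracts the locus count (a crude measure of
    information content beyond one allele per locus); ``ratio_snp_ssr`` is
    ``n_alleles(SNP) / n_alleles(SSR)`` rounded to 2 decimals when both
    marker types are present.
    """
    if g.n_individuals == 0 or g.n_loci == 0:
        raise ValidationError("summarize_alleles: empty dataset")
    out: dict = {}
    for mtype in (SSR, SNP):
        idx = g.locus_indices(mtype)
        if not idx:
            continue
        n_alleles = sum(len(g.observed_alleles(l)) for l in idx)
        out[mtype] = {
            "n_loci": len(idx),
            "n_alleles": n_alleles,
            "alleles_minus_loci": n_alleles - len(idx),
        }
    if SSR in out and SNP in out and out[SSR]["n_alleles"] > 0:
        out["ratio_snp_ssr"] = round(out[SNP]["n_alleles"] / out[SSR]["n_alleles"], 2)
    return out


# ---------------------------------------------------------------------------
# membership matrices
# ---------------------------------------------------------------------------


def read_membership_matrix(path: str | Path, run_id: Optional[str] = None) -> MembershipMatrix:
    """Read a Q matrix CSV (``ind,q1..qK``); rows are renormalized if their
    sum deviates from 1 by at most 1e-6, otherwise an error is raised."""
    path = Path(path)
    rid = run_id
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"^#\s*run_id:\s*(\S+)", line)
                if m and rid is None:
                    rid = m.group(1)
                continue
            rows.append(next(csv.reader([line])))
    if not rows:
        raise FormatError(f"{path}: empty membership matrix")
    header = rows[0]
    if header[0].lower() != "ind":
        raise FormatError(f"{path}: first column must be 'ind'")
    individuals = [r[0] for r in rows[1:]]
    try:
        q = np.array([[float(x) for x in r[1:]] for r in rows[1:]], dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric q value") from exc
    sums = q.sum(axis=1)
    bad = np.abs(sums - 1.0) > 1e-6
    if np.any(bad):
        ind = individuals[int(np.argmax(bad))]
        raise ValidationError(f"{path}: q row for {ind!r} sums to {sums[bad][0]:.8f}")
    q = q / sums[:, None]
    return MembershipMatrix(rid or path.stem, individuals, q)


def write_membership_matrix(m: MembershipMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# run_id: {m.run_id}\n")
        writer = csv.writer(fh)
        writer.writerow(["ind"] + [f"q{k + 1}" for k in range(m.K)])
        for ind, row in zip(m.individuals, m.q):
            writer.writerow([ind] + [f"{v:.10f}" for v in row])


# ---------------------------------------------------------------------------
# phased haplotypes
# ---------------------------------------------------------------------------


def read_phased_fasta(path: str | Path) -> PhasedHaplotypeSet:
    """Read phased, aligned haplotypes; FASTA headers are ``INDID|1`` / ``INDID|2``."""
    path = Path(path)
    per_ind: dict[str, dict[str, str]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if "|" not in record.id:
            raise FormatError(f"{path}: header {record.id!r} lacks '|phase' suffix")
        ind, phase = record.id.rsplit("|", 1)
        if phase not in ("1", "2"):
            raise FormatError(f"{path}: header {record.id!r} phase must be 1 or 2")
        per_ind.setdefault(ind, {})[phase] = str(record.seq).upper()
    individuals = list(per_ind)
    sequences: dict[str, tuple[str, str]] = {}
    for ind, phases in per_ind.items():
        if set(phases) != {"1", "2"}:
            raise ValidationError(
                f"{path}: individual {ind!r} has {len(phases)} haplotype(s), expected 2"
            )
        sequences[ind] = (phases["1"], phases["2"])
    if not sequences:
        raise FormatError(f"{path}: no sequences")
    return PhasedHaplotypeSet(individuals, sequences)


def write_phased_fasta(h: PhasedHaplotypeSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ind in h.individuals:
            for phase, seq in zip(("1", "2"), h.sequences[ind]):
                fh.write(f">{ind}|{phase}\n{seq}\n")


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


def read_distance_csv(path: str | Path) -> LabeledDistanceMatrix:
    """Read a labelled square CSV; asymmetry beyond 1e-9 is an error, smaller
    asymmetry is averaged out."""
    path = Path(path)
    metric = "custom"
    global_value: Optional[float] = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"^#\s*metric:\s*(\S+)", line)
                if m:
                    metric = m.group(1)
                m = re.match(r"^#\s*global:\s*(\S+)", line)
                if m:
                    global_value = float(m.group(1))
                continue
            rows.append(next(csv.reader([line])))
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    labels = rows[0][1:]
    n = len(labels)
    if len(rows) != n + 1:
        raise FormatError(f"{path}: expected {n} data rows, found {len(rows) - 1}")
    values = np.empty((n, n))
    for i, row in enumerate(rows[1:]):
        if row[0] != labels[i]:
            raise FormatError(f"{path}: row label {row[0]!r} != column label {labels[i]!r}")
        values[i] = [float(x) for x in row[1:]]
    if np.any(np.abs(values - values.T) > 1e-9):
        raise ValidationError(f"{path}: matrix asymmetric beyond 1e-9")
    values = (values + values.T) / 2.0
    return LabeledDistanceMatrix(labels, values, metric, global_value)


def write_distance_csv(d: LabeledDistanceMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# metric: {d.metric_name}\n")
        if d.global_value is not None:
            fh.write(f"# global: {d.global_value:.6f}\n")
        writer = csv.writer(fh)
        writer.writerow([""] + d.labels)
        for label, row in zip(d.labels, d.values):
            writer.writerow([label] + [f"{v:.6f}" for v in row])
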