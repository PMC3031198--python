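"""Sampling configuration, priors, alignment parsing and reference-table I/O.

The inference pipeline compares an observed multi-taxon, multi-locus data set
against coalescent simulations that match it *exactly* in sampling
configuration: number of taxon-pairs, loci per pair, sample sizes per
population, and alignment lengths.  Everything downstream (simulator, summary
statistics, reference table) is therefore keyed to a :class:`SamplingConfig`.

Sequence data can be supplied as FASTA (one file per locus, population
membership encoded as ``pop=1`` / ``pop=2`` in the description line) or as
IM-format files.  The reference table of prior simulations is stored as
tab-delimited text with a single JSON header line carrying the column
manifest, so observed and simulated statistic vectors always align
coordinate-by-coordinate.
"""

from __future__ import annotations

import configparser
import json
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "LocusConfig",
    "SamplingConfig",
    "PriorSpec",
    "MigrationModel",
    "LocusAlignment",
    "ReferenceTable",
    "parse_fasta_pair",
    "parse_im",
    "write_reference_table",
    "read_reference_table",
    "read_run_config",
    "write_run_config",
]

SUBST_MODELS = ("JC", "F81", "HKY")

# nucleotide integer codes used throughout the package
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_DECODE = np.array(["A", "C", "G", "T"])
_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE.items():
    _CODE_TABLE[ord(_b)] = _c
    _CODE_TABLE[ord(_b.lower())] = _c


def encode_sequences(seqs: Sequence[str]) -> np.ndarray:
    """Encode ACGT strings into a (n, L) uint8 matrix; 255 marks non-ACGT."""
    if not seqs:
        raise ValueError("no sequences given")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences have unequal lengths")
    raw = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw].reshape(len(seqs), L)


def decode_matrix(matrix: np.ndarray) -> list[str]:
    return ["".join(_DECODE[row]) for row in matrix]


@dataclass(frozen=True)
class LocusConfig:
    """Sampling configuration of one locus of one taxon-pair."""

    n1: int
    n2: int
    length: int
    inheritance_scalar: float = 1.0
    rate_scalar_fixed: float | None = None
    subst_model: str = "F81"
    kappa: float = 2.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    name: str = ""

    def __post_init__(self):
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("sample sizes must be >= 1")
        if self.length < 1:
            raise ValueError("locus length must be >= 1")
        if self.inheritance_scalar <= 0:
            raise ValueError("inheritance scalar must be > 0")
        if self.subst_model not in SUBST_MODELS:
            raise ValueError(f"unknown substitution model {self.subst_model!r}")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or (freqs < 0).any():
            raise ValueError("base_freqs must be 4 non-negative values")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1")
        if self.subst_model == "JC" and not np.allclose(freqs, 0.25, atol=1e-9):
            raise ValueError("JC requires equal base frequencies")

    @property
    def n_total(self) -> int:
        return self.n1 + self.n2


@dataclass(frozen=True)
class SamplingConfig:
    """Loci sampled per taxon-pair; the layout key for the whole pipeline.

    ``pairs[y]`` is the list of loci sampled from taxon-pair ``y``.  Different
    pairs may carry different numbers of loci of differing lengths and sample
    sizes.
    """

    pairs: tuple[tuple[LocusConfig, ...], ...]
    pair_names: tuple[str, ...] = ()

    def __post_init__(self):
        pairs = tuple(tuple(loci) for loci in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        if len(pairs) < 1:
            raise ValueError("at least one taxon-pair required")
        if any(len(loci) < 1 for loci in pairs):
            raise ValueError("every taxon-pair needs at least one locus")
        names = tuple(self.pair_names) or tuple(
            f"pair{i + 1}" for i in range(len(pairs))
        )
        if len(names) != len(pairs):
            raise ValueError("pair_names length mismatch")
        object.__setattr__(self, "pair_names", names)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_loci(self) -> tuple[int, ...]:
        return tuple(len(loci) for loci in self.pairs)


def uniform_config(
    n_pairs: int,
    n_loci: int,
    n1: int,
    n2: int,
    length: int,
    **locus_kwargs,
) -> SamplingConfig:
    """Convenience constructor: identical loci across all taxon-pairs."""
    locus = LocusConfig(n1=n1, n2=n2, length=length, **locus_kwargs)
    return SamplingConfig(pairs=tuple((locus,) * n_loci for _ in range(n_pairs)))


@dataclass(frozen=True)
class MigrationModel:
    """One candidate migration model: Nm drawn uniformly from [lo, hi].

    ``lo == hi == 0`` encodes the isolation model (no post-divergence gene
    flow).  Nm is the effective number of migrants per generation, symmetric
    between the descendant populations.
    """

    label: str
    nm_lo: float
    nm_hi: float

    def __post_init__(self):
        if not (0 <= self.nm_lo <= self.nm_hi):
            raise ValueError("need 0 <= nm_lo <= nm_hi")

    @property
    def is_isolation(self) -> bool:
        return self.nm_hi == 0


def _check_range(name, rng, lo_min=0.0):
    lo, hi = rng
    if not (lo_min <= lo <= hi):
        raise ValueError(f"invalid range for {name}: {rng}")


@dataclass(frozen=True)
class PriorSpec:
    """Hyper-prior bounds of the hierarchical divergence-with-migration model.

    All θ are per-site population mutation rates (4Nμ); τ is in coalescent
    units of 4N generations where N is the sum of current descendant
    population sizes.  Descendant sizes at the split (θ_A1, θ_A2) and growth
    onset times (τ_B1, τ_B2) are parameterized as uniform fractions of θ_A
    and τ respectively, which enforces τ_Bi ≤ τ by construction.
    """

    tau_range: tuple[float, float] = (0.0, 5.0)
    theta_a_range: tuple[float, float] = (0.0001, 0.01)
    theta_b_range: tuple[float, float] = (0.0001, 0.01)
    size_fraction_range: tuple[float, float] = (0.1, 1.0)
    growth_time_fraction_range: tuple[float, float] = (0.0, 1.0)
    migration_models: tuple[MigrationModel, ...] = (
        MigrationModel("isolation", 0.0, 0.0),
    )
    alpha_range: tuple[float, float] = (1.0, 20.0)
    rate_het_enabled: bool = True
    psi_fixed: int | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "migration_models", tuple(self.migration_models)
        )
        _check_range("tau_range", self.tau_range)
        _check_range("theta_a_range", self.theta_a_range)
        _check_range("theta_b_range", self.theta_b_range)
        _check_range("size_fraction_range", self.size_fraction_range)
        _check_range("growth_time_fraction_range", self.growth_time_fraction_range)
        _check_range("alpha_range", self.alpha_range)
        if not self.migration_models:
            raise ValueError("at least one migration model required")
        if self.psi_fixed is not None and self.psi_fixed < 1:
            raise ValueError("psi_fixed must be >= 1")

    def with_models(self, models: Iterable[MigrationModel]) -> "PriorSpec":
        return replace(self, migration_models=tuple(models))


@dataclass
class LocusAlignment:
    """Gap-free aligned sequences for one locus with population labels."""

    matrix: np.ndarray  # (n, L) uint8 codes 0..3
    pop_labels: np.ndarray  # (n,) values in {1, 2}
    pair_id: str = ""
    locus_id: str = ""

    def __post_init__(self):
        self.matrix = np.ascontiguousarray(self.matrix, dtype=np.uint8)
        self.pop_labels = np.asarray(self.pop_labels, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if self.pop_labels.shape[0] != self.matrix.shape[0]:
            raise ValueError("one population label per sequence required")
        if not np.isin(self.pop_labels, (1, 2)).all():
            raise ValueError("population labels must be 1 or 2")

    @classmethod
    def from_sequences(cls, seqs, pop_labels, pair_id="", locus_id=""):
        return cls(encode_sequences(list(seqs)), np.asarray(pop_labels),
                   pair_id=pair_id, locus_id=locus_id)

    @property
    def sequences(self) -> list[str]:
        return decode_matrix(self.matrix)

    @property
    def n1(self) -> int:
        return int((self.pop_labels == 1).sum())

    @property
    def n2(self) -> int:
        return int((self.pop_labels == 2).sum())

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def drop_incomplete_columns(self) -> "LocusAlignment":
        """Drop columns where any sequence carries a gap/ambiguity code."""
        keep = (self.matrix <= 3).all(axis=0)
        return LocusAlignment(self.matrix[:, keep], self.pop_labels,
                              self.pair_id, self.locus_id)


# ---------------------------------------------------------------------------
# FASTA parsing

def _pop_from_description(desc: str) -> int:
    for token in desc.replace(",", " ").split():
        if token.startswith("pop="):
            value = token[4:]
            if value in ("1", "2"):
                return int(value)
            raise ValueError(f"invalid population tag {token!r}")
    raise ValueError(f"no 'pop=' tag found in FASTA header {desc!r}")


def parse_fasta_pair(paths, pair_id, config=None):
    """Parse one taxon-pair's loci from FASTA files (one file per locus).

    Population membership is read from a ``pop=1`` / ``pop=2`` token in the
    description line.  Columns containing any non-ACGT symbol in any sequence
    (gaps, ambiguity codes) are removed listwise before any statistic is
    computed, so the effective alignment length may be smaller than the file's.
    When ``config`` (the taxon-pair's locus list) is given, per-locus sample
    sizes are checked against it.
    """
    alignments = []
    for i, path in enumerate(paths):
        locus_id = f"locus{i + 1}"
        seqs, labels = [], []
        handle = path if hasattr(path, "read") else open(path)
        try:
            for record in SeqIO.parse(handle, "fasta"):
                labels.append(_pop_from_description(record.description))
                seqs.append(str(record.seq).upper())
        finally:
            if not hasattr(path, "read"):
                handle.close()
        if len(seqs) < 2:
            raise ValueError(f"{pair_id}/{locus_id}: fewer than 2 sequences")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(
                f"{pair_id}/{locus_id}: unequal sequence lengths {sorted(lengths)}"
            )
        aln = LocusAlignment(
            encode_sequences(seqs), np.array(labels), pair_id, locus_id
        ).drop_incomplete_columns()
        alignments.append(aln)
    if config is not None:
        loci = list(config)
        if len(loci) != len(alignments):
            raise ValueError(
                f"{pair_id}: expected {len(loci)} loci, parsed {len(alignments)}"
            )
        for aln, lc in zip(alignments, loci):
            if (aln.n1, aln.n2) != (lc.n1, lc.n2):
                raise ValueError(
                    f"{pair_id}/{aln.locus_id}: sample sizes ({aln.n1},{aln.n2}) "
                    f"do not match configuration ({lc.n1},{lc.n2})"
                )
    return alignments


# ---------------------------------------------------------------------------
# IM format parsing

_IM_MODEL_CODES = {"I": "F81", "H": "HKY", "J": "JC"}


def parse_im(source):
    """Parse an IM-format input file into locus configurations + alignments.

    Layout: a title line, a line with the two population names, a line with
    the number of loci; then per locus a header line
    ``name n1 n2 length inheritance_scalar model_code`` followed by the
    ``n1 + n2`` sequence lines (``name  sequence``), population 1 first.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if len(lines) < 3:
        raise ValueError("truncated IM file: missing header")
    pop_names = lines[1].split()
    try:
        n_loci = int(lines[2].split()[0])
    except ValueError as exc:
        raise ValueError("IM file: cannot parse locus count") from exc
    pos = 3
    locus_configs, alignments = [], []
    for k in range(n_loci):
        if pos >= len(lines):
            raise ValueError(
                f"truncated IM file: locus {k + 1} of {n_loci} missing"
            )
        fields = lines[pos].split()
        if len(fields) < 6:
            raise ValueError(f"IM locus header malformed: {lines[pos]!r}")
        name = fields[0]
        n1, n2, length = int(fields[1]), int(fields[2]), int(fields[3])
        scalar = float(fields[4])
        code = fields[5][0].upper()
        if code not in _IM_MODEL_CODES:
            raise ValueError(f"unknown IM mutation model code {fields[5]!r}")
        pos += 1
        n_total = n1 + n2
        if pos + n_total > len(lines):
            raise ValueError(f"truncated IM file: sequences missing for locus {name}")
        seqs, labels = [], []
        for j in range(n_total):
            parts = lines[pos + j].split()
            if len(parts) < 2:
                # IM allows fixed-width name field; fall back to 10-char split
                parts = [lines[pos + j][:10].strip(), lines[pos + j][10:].strip()]
            seqs.append(parts[-1].upper())
            labels.append(1 if j < n1 else 2)
        pos += n_total
        aln = LocusAlignment(
            encode_sequences(seqs), np.array(labels), pop_names[0] if pop_names else "",
            name,
        ).drop_incomplete_columns()
        alignments.append(aln)
        locus_configs.append(
            LocusConfig(
                n1=n1, n2=n2, length=aln.length,
                inheritance_scalar=scalar,
                subst_model=_IM_MODEL_CODES[code], name=name,
            )
        )
    return locus_configs, alignments


# ---------------------------------------------------------------------------
# Reference table I/O

@dataclass
class ReferenceTable:
    """Prior simulations: hyper-parameter records paired with D_m vectors.

    ``params`` holds one row per simulation (model indicator, Ψ, E(τ), Ω and
    the per-pair τ values); ``stats`` is the matching (rows × coordinates)
    matrix of flattened, π_b-sorted moment vectors.  ``manifest`` names every
    statistic coordinate and is a pure function of the sampling configuration
    and the chosen statistic classes, so observed vectors computed under the
    same configuration align column-for-column.
    """

    params: pd.DataFrame
    stats: np.ndarray
    manifest: dict

    def __post_init__(self):
        self.stats = np.asarray(self.stats, dtype=float)
        if self.stats.ndim != 2:
            raise ValueError("stats must be a 2-D matrix")
        if len(self.params) != self.stats.shape[0]:
            raise ValueError("params and stats row counts differ")
        cols = self.manifest.get("stat_columns")
        if cols is not None and len(cols) != self.stats.shape[1]:
            raise ValueError("manifest stat_columns do not match stats width")

    @property
    def n_rows(self) -> int:
        return self.stats.shape[0]

    def subset(self, mask) -> "ReferenceTable":
        mask = np.asarray(mask)
        return ReferenceTable(
            self.params.iloc[mask].reset_index(drop=True),
            self.stats[mask],
            self.manifest,
        )


_HEADER_PREFIX = "#codiv-reference-table\t"


def write_reference_table(table: ReferenceTable, sink) -> None:
    """Write a reference table as TSV with a JSON manifest header line."""
    own = not hasattr(sink, "write")
    fh = open(sink, "w") if own else sink
    try:
        fh.write(_HEADER_PREFIX + json.dumps(table.manifest, sort_keys=True) + "\n")
        stat_cols = list(table.manifest["stat_columns"])
        frame = pd.concat(
            [table.params.reset_index(drop=True),
             pd.DataFrame(table.stats, columns=stat_cols)],
            axis=1,
        )
        frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    finally:
        if own:
            fh.close()


def read_reference_table(source) -> ReferenceTable:
    own = not hasattr(source, "read")
    fh = open(source) if own else source
    try:
        header = fh.readline()
        if not header.startswith(_HEADER_PREFIX):
            raise ValueError("not a codiv reference table (missing manifest header)")
        manifest = json.loads(header[len(_HEADER_PREFIX):])
        frame = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    finally:
        if own:
            fh.close()
    stat_cols = list(manifest["stat_columns"])
    missing = [c for c in stat_cols if c not in frame.columns]
    if missing:
        raise ValueError(f"reference table columns missing: {missing[:3]}")
    stats = frame[stat_cols].to_numpy(dtype=float)
    params = frame.drop(columns=stat_cols)
    return ReferenceTable(params, stats, manifest)


# ---------------------------------------------------------------------------
# Run configuration (INI)

def _fmt_range(rng):
    return f"{rng[0]:g},{rng[1]:g}"


def _parse_range(text):
    lo, hi = (float(x) for x in text.split(","))
    return (lo, hi)


def write_run_config(config: SamplingConfig, prior: PriorSpec, sink) -> None:
    cp = configparser.ConfigParser()
    cp["priors"] = {
        "tau": _fmt_range(prior.tau_range),
        "theta_a": _fmt_range(prior.theta_a_range),
        "theta_b": _fmt_range(prior.theta_b_range),
        "size_fraction": _fmt_range(prior.size_fraction_range),
        "growth_time_fraction": _fmt_range(prior.growth_time_fraction_range),
        "alpha": _fmt_range(prior.alpha_range),
        "rate_het": str(prior.rate_het_enabled).lower(),
        "migration_models": "; ".join(
            f"{m.label}:{m.nm_lo:g}:{m.nm_hi:g}" for m in prior.migration_models
        ),
    }
    if prior.psi_fixed is not None:
        cp["priors"]["psi_fixed"] = str(prior.psi_fixed)
    for name, loci in zip(config.pair_names, config.pairs):
        section = f"pair:{name}"
        cp[section] = {}
        for i, lc in enumerate(loci):
            cp[section][f"locus{i + 1}"] = (
                f"{lc.name or f'locus{i + 1}'},{lc.n1},{lc.n2},{lc.length},"
                f"{lc.inheritance_scalar:g},{lc.subst_model},{lc.kappa:g}"
            )
    own = not hasattr(sink, "write")
    fh = open(sink, "w") if own else sink
    try:
        cp.write(fh)
    finally:
        if own:
            fh.close()


def read_run_config(source) -> tuple[SamplingConfig, PriorSpec]:
    cp = configparser.ConfigParser()
    if hasattr(source, "read") and not isinstance(source, str):
        cp.read_file(source)
    else:
        if not cp.read(source):
            raise ValueError(f"cannot read run configuration {source!r}")
    pr = cp["priors"]
    models = []
    for item in pr.get("migration_models", "isolation:0:0").split(";"):
        label, lo, hi = item.strip().split(":")
        models.append(MigrationModel(label, float(lo), float(hi)))
    prior = PriorSpec(
        tau_range=_parse_range(pr.get("tau", "0,5")),
        theta_a_range=_parse_range(pr.get("theta_a", "0.0001,0.01")),
        theta_b_range=_parse_range(pr.get("theta_b", "0.0001,0.01")),
        size_fraction_range=_parse_range(pr.get("size_fraction", "0.1,1")),
        growth_time_fraction_range=_parse_range(
            pr.get("growth_time_fraction", "0,1")),
        alpha_range=_parse_range(pr.get("alpha", "1,20")),
        rate_het_enabled=pr.getboolean("rate_het", fallback=True),
        migration_models=tuple(models),
        psi_fixed=pr.getint("psi_fixed", fallback=None),
    )
    pairs, names = [], []
    for section in cp.sections():
        if not section.startswith("pair:"):
            continue
        names.append(section[5:])
        loci = []
        for _, value in sorted(cp[section].items()):
            f = value.split(",")
            loci.append(
                LocusConfig(
                    name=f[0], n1=int(f[1]), n2=int(f[2]), length=int(f[3]),
                    inheritance_scalar=float(f[4]), subst_model=f[5].strip(),
                    kappa=float(f[6]) if len(f) > 6 else 2.0,
                )
            )
        pairs.append(tuple(loci))
    if not pairs:
        raise ValueError("run configuration defines no taxon-pairs")
    return SamplingConfig(tuple(pairs), tuple(names)), prior
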