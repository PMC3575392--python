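"""Reading and writing expression matrices, clinical tables, and gene lists.

Expression matrices are tab-delimited text: first column holds gene (or
probe) identifiers, the header row holds sample identifiers, and the body is
numeric (empty cells or ``NA``-like tokens are treated as missing).  Probe
level matrices are collapsed to gene level by keeping, per gene, the probe
with the highest across-sample variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionCohort",
    "CandidateSets",
    "ProbeMap",
    "read_expression",
    "read_clinical",
    "read_gene_list",
    "read_probe_map",
    "collapse_probes",
    "write_expression",
]

_NA_TOKENS = {"", "NA", "N/A", "NaN", "nan", "null", "NULL"}


class FormatError(ValueError):
    """Malformed input file; the message carries the offending location."""


@dataclass
class ExpressionCohort:
    """Gene-by-sample log-expression with optional survival outcome.

    Parameters
    ----------
    cohort_id : str
        Label used in reports and meta-analysis weights.
    genes : list of str
        Ordered, unique gene symbols (rows of ``values``).
    samples : list of str
        Ordered, unique sample identifiers (columns of ``values``).
    values : ndarray of shape (n_genes, n_samples)
        Log-scale expression; NaN marks a missing measurement.
    time : ndarray of shape (n_samples,), optional
        Follow-up time in years (non-negative).
    event : ndarray of shape (n_samples,), optional
        Event indicator, 0 (censored) or 1 (event).
    covariates : DataFrame, optional
        Per-sample categorical/ordinal covariates indexed by sample ID;
        missing entries allowed.
    """

    cohort_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    time: np.ndarray | None = None
    event: np.ndarray | None = None
    covariates: pd.DataFrame | None = None
    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"cohort {self.cohort_id!r}: matrix shape {self.values.shape} does not "
                f"match {len(self.genes)} genes x {len(self.samples)} samples"
            )
        dup = _first_duplicate(self.genes)
        if dup is not None:
            raise ValueError(f"cohort {self.cohort_id!r}: duplicate gene symbol {dup!r}")
        dup = _first_duplicate(self.samples)
        if dup is not None:
            raise ValueError(f"cohort {self.cohort_id!r}: duplicate sample ID {dup!r}")
        if (self.time is None) != (self.event is None):
            raise ValueError("time and event must be supplied together")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event, dtype=int)
            if self.time.shape != (len(self.samples),) or self.event.shape != (len(self.samples),):
                raise ValueError("outcome arrays must have one entry per sample")
            if np.any(self.time < 0):
                raise ValueError("negative follow-up time")
            if not np.isin(self.event, (0, 1)).all():
                raise ValueError("event indicator must be 0 or 1")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def has_outcome(self) -> bool:
        return self.time is not None

    def gene_rows(self, genes) -> np.ndarray:
        """Row indices for ``genes``; raises ``KeyError`` for unknown symbols."""
        return np.array([self._gene_index[g] for g in genes], dtype=int)

    def expression(self, genes) -> np.ndarray:
        """Sub-matrix (len(genes) x n_samples) for the requested genes."""
        return self.values[self.gene_rows(genes)]

    def attach_clinical(self, clinical: pd.DataFrame) -> "ExpressionCohort":
        """Return a copy with outcome/covariates joined from a clinical table.

        ``clinical`` must be indexed by sample ID and carry ``time_years``
        and ``event`` columns; remaining columns become covariates.  Samples
        absent from the table get a NaN time, which excludes them from
        survival analysis downstream.
        """
        sub = clinical.reindex(self.samples)
        time = sub["time_years"].to_numpy(dtype=float)
        event = np.nan_to_num(sub["event"].to_numpy(dtype=float), nan=0).astype(int)
        cov = sub.drop(columns=["time_years", "event"])
        out = ExpressionCohort(
            cohort_id=self.cohort_id,
            genes=list(self.genes),
            samples=list(self.samples),
            values=self.values.copy(),
        )
        # bypass the 0/1 validation path: NaN time marks "no outcome recorded"
        out.time = time
        out.event = event
        out.covariates = cov if cov.shape[1] else None
        return out


@dataclass(frozen=True)
class CandidateSets:
    """The two pre-defined candidate gene lists.

    ``poor`` holds markers whose relatively high expression is hypothesized
    to confer poor prognosis; ``good`` the converse.  The lists must be
    disjoint and each must contain at least two genes.
    """

    poor: tuple[str, ...]
    good: tuple[str, ...]

    def __init__(self, poor, good):
        poor = tuple(poor)
        good = tuple(good)
        if len(poor) < 2 or len(good) < 2:
            raise ValueError("each candidate set needs at least 2 genes")
        if _first_duplicate(poor) or _first_duplicate(good):
            raise ValueError("candidate sets must not contain duplicates")
        overlap = set(poor) & set(good)
        if overlap:
            raise ValueError(f"candidate sets overlap: {sorted(overlap)}")
        object.__setattr__(self, "poor", poor)
        object.__setattr__(self, "good", good)


@dataclass(frozen=True)
class ProbeMap:
    """probe ID -> gene symbol mapping (one gene per probe)."""

    probe_to_gene: dict[str, str]

    def gene(self, probe: str) -> str:
        return self.probe_to_gene[probe]


def _first_duplicate(items) -> str | None:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def _parse_cell(token: str, path: str, row: int, col: str) -> float:
    token = token.strip()
    if token in _NA_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"{path}: non-numeric value {token!r} at data row {row}, column {col!r}"
        ) from None


def read_expression(path, probe_map: ProbeMap | None = None, cohort_id: str | None = None) -> ExpressionCohort:
    """Read a tab-delimited expression matrix.

    First column: gene/probe IDs; header row: sample IDs; body numeric with
    NA tokens allowed.  When ``probe_map`` is given, rows are treated as
    probes and collapsed to genes via :func:`collapse_probes`.
    """
    path = str(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header or "\t" not in header:
            raise FormatError(f"{path}: malformed header (expected tab-delimited sample IDs)")
        fields = header.split("\t")
        samples = fields[1:]
        if any(not s.strip() for s in samples):
            raise FormatError(f"{path}: empty sample ID in header")
        dup = _first_duplicate(samples)
        if dup is not None:
            raise FormatError(f"{path}: duplicate sample ID {dup!r} in header")
        ids: list[str] = []
        rows: list[list[float]] = []
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(samples) + 1:
                raise FormatError(
                    f"{path}: data row {i} has {len(parts) - 1} values, expected {len(samples)}"
                )
            ids.append(parts[0])
            rows.append([_parse_cell(t, path, i, samples[j]) for j, t in enumerate(parts[1:])])
    values = np.array(rows, dtype=float) if rows else np.empty((0, len(samples)))
    cid = cohort_id if cohort_id is not None else path
    if probe_map is not None:
        genes, values = collapse_probes(ids, values, probe_map)
    else:
        genes = ids
    return ExpressionCohort(cohort_id=cid, genes=genes, samples=samples, values=values)


def collapse_probes(probes, values, probe_map: ProbeMap) -> tuple[list[str], np.ndarray]:
    """Collapse a probe x sample matrix to gene level.

    For each gene the retained row is the probe with maximal across-sample
    variance (sample variance, n-1 denominator, missing values excluded);
    exact variance ties are broken by lexicographic probe ID.  Output gene
    order follows first appearance of each gene in probe order.  Rows are
    copied verbatim — never averaged.
    """
    values = np.asarray(values, dtype=float)
    unmapped = [p for p in probes if p not in probe_map.probe_to_gene]
    if unmapped:
        raise KeyError(f"probes missing from probe map: {unmapped[:5]}")
    with np.errstate(invalid="ignore"):
        variances = np.array([
            np.nanvar(row, ddof=1) if np.sum(~np.isnan(row)) >= 2 else 0.0
            for row in values
        ])
    best: dict[str, tuple[float, str, int]] = {}
    order: list[str] = []
    for i, probe in enumerate(probes):
        gene = probe_map.gene(probe)
        if gene not in best:
            order.append(gene)
        key = (-variances[i], probe)  # max variance, then lexicographically first probe
        if gene not in best or key < best[gene][:2]:
            best[gene] = (key[0], key[1], i)
    idx = [best[g][2] for g in order]
    return order, values[idx].copy()


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical table: sample_id, time_years, event, then covariates."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = {"sample_id", "time_years", "event"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    dup = _first_duplicate(df["sample_id"].tolist())
    if dup is not None:
        raise FormatError(f"{path}: duplicate sample ID {dup!r}")
    df = df.set_index("sample_id")
    bad = df["time_years"].dropna() < 0
    if bad.any():
        raise FormatError(f"{path}: negative time for sample {bad[bad].index[0]!r}")
    ev = df["event"].dropna()
    if not ev.isin((0, 1)).all():
        raise FormatError(f"{path}: event values must be 0/1")
    return df


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    dup = _first_duplicate(genes)
    if dup is not None:
        raise FormatError(f"{path}: duplicate gene {dup!r}")
    return genes


def read_probe_map(path) -> ProbeMap:
    """Two-column TSV: probe_id, gene symbol."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {i}: expected probe_id<TAB>gene")
            if parts[0] in mapping:
                raise FormatError(f"{path}: probe {parts[0]!r} mapped twice")
            mapping[parts[0]] = parts[1]
    return ProbeMap(mapping)


def write_expression(cohort: ExpressionCohort, path) -> None:
    """Write a cohort back to the tab-delimited matrix format (full precision)."""
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(cohort.samples) + "\n")
        for g, row in zip(cohort.genes, cohort.values):
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(g + "\t" + "\t".join(cells) + "\n")


def write_clinical(cohort: ExpressionCohort, path) -> None:
    """Write outcome (+ covariates) of a cohort as a clinical TSV."""
    if not cohort.has_outcome():
        raise ValueError("cohort has no outcome to write")
    df = pd.DataFrame({
        "sample_id": cohort.samples,
        "time_years": cohort.time,
        "event": cohort.event,
    })
    if cohort.covariates is not None:
        for c in cohort.covariates.columns:
            df[c] = cohort.covariates[c].to_numpy()
    df.to_csv(path, sep="\t", index=False)
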