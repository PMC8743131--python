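"""GWAS summary statistics: I/O, validation, instrument selection, LD clumping.

Summary statistics are held as a :class:`SummaryStats` object wrapping a
pandas DataFrame with canonical columns.  LD is supplied as a local
:class:`LDTable` (pairwise r-squared) rather than queried from a reference
panel service, so the whole instrument-selection stage runs offline.
Coordinates are 1-based; the clumping window test is
``|pos_a - pos_b| <= window_kb * 1000`` on the same chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from mrpipe.errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical column order for summary-statistic tables
CANONICAL_COLUMNS = [
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: default file-header -> canonical-field mapping (PLINK-style headers)
DEFAULT_COLUMN_MAP = {
    "SNP": "variant_id",
    "CHR": "chromosome",
    "BP": "position",
    "A1": "effect_allele",
    "A2": "other_allele",
    "EAF": "eaf",
    "BETA": "beta",
    "SE": "se",
    "P": "pvalue",
    "N": "n",
}

_MANDATORY = ["variant_id", "chromosome", "position", "effect_allele",
              "other_allele", "beta", "se", "pvalue"]


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP record.

    Alleles are single nucleotides; multi-allelic variants and indels are
    outside the scope of this package.  ``eaf`` is the effect-allele
    frequency, absent in many disease GWAS releases.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise DataError(
                f"{self.variant_id}: alleles must be single nucleotides in A/C/G/T, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.variant_id}: effect and other allele are identical")
        if self.position <= 0:
            raise DataError(f"{self.variant_id}: position must be positive")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise DataError(f"{self.variant_id}: eaf must lie in (0, 1)")


@dataclass
class SummaryStats:
    """One trait's per-variant association results.

    ``table`` has the canonical columns of :data:`CANONICAL_COLUMNS`; betas
    are on the trait scale (log-odds for binary traits, SD units for
    continuous traits).  One row per ``variant_id``; ``se > 0`` everywhere.
    """

    trait_id: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.table.columns]
        if missing:
            raise ConfigurationError(f"{self.trait_id}: missing canonical columns {missing}")
        dup = self.table["variant_id"].duplicated()
        if dup.any():
            name = self.table.loc[dup, "variant_id"].iloc[0]
            raise DataError(f"{self.trait_id}: duplicate variant_id {name!r}")
        if (self.table["se"] <= 0).any():
            bad = self.table.loc[self.table["se"] <= 0, "variant_id"].iloc[0]
            raise DataError(f"{self.trait_id}: non-positive se for {bad!r}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()

    def get(self, variant_id: str) -> pd.Series:
        rows = self.table[self.table["variant_id"] == variant_id]
        if rows.empty:
            raise KeyError(variant_id)
        return rows.iloc[0]

    def subset(self, variant_ids: Iterable[str]) -> "SummaryStats":
        """Restrict to the given variants, preserving current row order."""
        keep = set(variant_ids)
        return SummaryStats(self.trait_id, self.table[self.table["variant_id"].isin(keep)].copy())

    def validate_pvalues(self, tol_log10: float = 0.5) -> None:
        """Check reported p-values against the two-sided normal p of beta/se.

        GWAS files often carry truncated p-values, so the check compares
        log10 p to a tolerance and is off by default in :func:`read_sumstats`.
        """
        z = np.abs(self.table["beta"] / self.table["se"])
        implied = stats.norm.logsf(z) + np.log(2.0)
        implied_log10 = implied / np.log(10.0)
        reported_log10 = np.log10(np.clip(self.table["pvalue"], 1e-320, 1.0))
        bad = np.abs(implied_log10 - reported_log10) > tol_log10
        if bad.any():
            name = self.table.loc[np.asarray(bad), "variant_id"].iloc[0]
            raise DataError(
                f"{self.trait_id}: reported p-value inconsistent with beta/se for {name!r}"
            )


class LDTable:
    """Symmetric pairwise r-squared lookup.

    Absent pairs are treated as unlinked (r2 = 0); the diagonal is
    implicitly 1.  Backed by a dict keyed on sorted id tuples.
    """

    def __init__(self, pairs: Optional[Mapping[tuple[str, str], float]] = None,
                 window_kb: int = 10_000) -> None:
        if window_kb <= 0:
            raise ConfigurationError("window_kb must be positive")
        self.window_kb = window_kb
        self._pairs: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self.set(a, b, r2)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise DataError(f"r2 out of [0,1] for pair ({a}, {b}): {r2}")
        if a != b:
            self._pairs[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._pairs.get(self._key(a, b), 0.0)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    def partners(self, a: str) -> dict[str, float]:
        """All variants with a recorded r2 to ``a``."""
        out = {}
        for (x, y), r2 in self._pairs.items():
            if x == a:
                out[y] = r2
            elif y == a:
                out[x] = r2
        return out

    @classmethod
    def read(cls, path: str | Path, window_kb: int = 10_000) -> "LDTable":
        """Read a three-column tab-delimited file (id_a, id_b, r2)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["id_a", "id_b", "r2"],
                         comment="#", dtype={"id_a": str, "id_b": str})
        table = cls(window_kb=window_kb)
        for a, b, r2 in df.itertuples(index=False):
            table.set(a, b, float(r2))
        return table

    def write(self, path: str | Path) -> None:
        rows = sorted((a, b, r2) for (a, b), r2 in self._pairs.items())
        with open(path, "w") as fh:
            for a, b, r2 in rows:
                fh.write(f"{a}\t{b}\t{r2:.6g}\n")


def read_sumstats(path: str | Path, trait_id: Optional[str] = None,
                  column_map: Optional[Mapping[str, str]] = None,
                  validate_pvalues: bool = False,
                  pvalue_tol_log10: float = 0.5) -> SummaryStats:
    """Read a tab- or comma-delimited summary-statistic file.

    Parameters
    ----------
    path
        File location; gzip-compressed files are read transparently.
    trait_id
        Label for the trait; defaults to the file stem.
    column_map
        File-header -> canonical-field mapping; defaults to
        :data:`DEFAULT_COLUMN_MAP` (SNP, CHR, BP, A1, A2, EAF, BETA, SE, P, N).
    validate_pvalues
        When true, reject rows whose reported p-value disagrees with the
        two-sided normal p of beta/se by more than ``pvalue_tol_log10`` in
        log10 units.

    Rows missing beta, se, or either allele are dropped and counted in the
    log.  Duplicate variant_ids raise :class:`DataError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", compression="infer")
    cmap = dict(column_map) if column_map is not None else dict(DEFAULT_COLUMN_MAP)
    rename = {src: dst for src, dst in cmap.items() if src in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ConfigurationError(
            f"{path.name}: mandatory columns missing after header mapping: {missing}"
        )
    for optional in ("eaf", "n"):
        if optional not in df.columns:
            df[optional] = np.nan
    df = df[CANONICAL_COLUMNS].copy()
    df["chromosome"] = df["chromosome"].astype(str)
    before = len(df)
    complete = df[["beta", "se", "effect_allele", "other_allele"]].notna().all(axis=1)
    df = df[complete]
    dropped = before - len(df)
    if dropped:
        logger.info("%s: dropped %d row(s) with missing beta/se/alleles", path.name, dropped)
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    biallelic = (df["effect_allele"].isin(VALID_ALLELES)
                 & df["other_allele"].isin(VALID_ALLELES)
                 & (df["effect_allele"] != df["other_allele"]))
    if (~biallelic).any():
        logger.info("%s: dropped %d non-biallelic-SNP row(s)", path.name, int((~biallelic).sum()))
        df = df[biallelic]
    ss = SummaryStats(trait_id or path.stem.replace(".tsv", "").replace(".gz", ""), df)
    if validate_pvalues:
        ss.validate_pvalues(tol_log10=pvalue_tol_log10)
    return ss


def write_sumstats(ss: SummaryStats, path: str | Path) -> None:
    """Write a SummaryStats table with the default headers, tab-delimited."""
    inverse = {v: k for k, v in DEFAULT_COLUMN_MAP.items()}
    out = ss.table.rename(columns=inverse)
    out.to_csv(path, sep="\t", index=False)


def select_instruments(ss: SummaryStats, p_threshold: float) -> SummaryStats:
    """Keep variants with pvalue <= p_threshold, preserving input order.

    The conventional genome-wide threshold is 5e-8; a relaxed threshold
    (e.g. 5e-7) can be used to gain instruments at the cost of potential
    weak-instrument bias.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ConfigurationError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    kept = ss.table[ss.table["pvalue"] <= p_threshold].copy()
    logger.info("%s: %d of %d variants pass p <= %g", ss.trait_id, len(kept), len(ss), p_threshold)
    return SummaryStats(ss.trait_id, kept)


def clump(ss: SummaryStats, ld: LDTable, r2_threshold: float = 0.01,
          window_kb: int = 10_000) -> SummaryStats:
    """Greedy p-value-ordered LD clumping.

    Variants are visited by ascending p-value (ties broken by ascending
    variant_id for determinism); a variant is accepted iff its r2 with every
    already-accepted variant on the same chromosome within ``window_kb`` is
    below ``r2_threshold``.  Pairs inside the window but absent from the LD
    table are treated as unlinked and logged once.

    Returns the accepted set sorted by p-value.
    """
    if not (0.0 < r2_threshold < 1.0):
        raise ConfigurationError(f"r2_threshold must lie in (0, 1), got {r2_threshold}")
    if window_kb <= 0:
        raise ConfigurationError(f"window_kb must be positive, got {window_kb}")
    window_bp = window_kb * 1000
    order = ss.table.sort_values(["pvalue", "variant_id"], kind="mergesort")
    accepted: list[tuple[str, str, int]] = []  # (variant_id, chromosome, position)
    accepted_ids: list[str] = []
    missing_pair_logged = False
    for row in order.itertuples(index=False):
        ok = True
        for aid, achrom, apos in accepted:
            if row.chromosome != achrom or abs(row.position - apos) > window_bp:
                continue
            if (row.variant_id, aid) not in ld and not missing_pair_logged:
                logger.info("clump: LD pair(s) within window absent from table; treated as r2=0")
                missing_pair_logged = True
            if ld.r2(row.variant_id, aid) >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append((row.variant_id, row.chromosome, row.position))
            accepted_ids.append(row.variant_id)
    out = order[order["variant_id"].isin(accepted_ids)].copy()
    logger.info("%s: clumping kept %d of %d variants", ss.trait_id, len(out), len(ss))
    return SummaryStats(ss.trait_id, out)


def find_proxy(target: str, candidates: SummaryStats, ld: LDTable,
               r2_min: float = 0.9) -> Optional[str]:
    """Best LD proxy for a variant missing from the outcome GWAS.

    Returns the candidate with maximal r2 to ``target`` among those with
    r2 strictly above ``r2_min``, or None if no candidate qualifies.  If the
    target is itself present in ``candidates`` it is returned unchanged.
    """
    if not (0.0 < r2_min < 1.0):
        raise ConfigurationError(f"r2_min must lie in (0, 1), got {r2_min}")
    available = set(candidates.variant_ids)
    if target in available:
        return target
    best_id, best_r2 = None, r2_min
    for other, r2 in sorted(ld.partners(target).items()):
        if other in available and r2 > best_r2:
            best_id, best_r2 = other, r2
    if best_id is not None:
        logger.info("proxy: %s -> %s (r2 = %.3f)", target, best_id, best_r2)
    return best_id
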