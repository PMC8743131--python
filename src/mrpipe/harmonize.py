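"""Allele harmonization of exposure and outcome effects.

Two-sample MR requires every trait's effect estimate to be expressed per
copy of the *same* effect allele at each variant.  This module aligns the
outcome (and any additional exposures) to the first exposure's effect
allele, handling swapped allele labels, complementary-strand reporting,
and palindromic (A/T, C/G) variants, whose strand cannot be resolved from
the alleles alone.  Palindromic variants are excluded unless effect-allele
frequencies are available on both sides and both are far enough from 0.5
to orient by minor-allele matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mrpipe.errors import DataError
from mrpipe.sumstats import SummaryStats

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_META_COLUMNS = ["variant_id", "chromosome", "position", "effect_allele", "other_allele"]


def classify_palindromic(variant, other_allele: Optional[str] = None) -> bool:
    """True iff the allele pair is {A,T} or {C,G} (strand-ambiguous).

    Accepts either a :class:`~mrpipe.sumstats.Variant` (or anything with
    ``effect_allele``/``other_allele`` attributes) or two allele strings.
    """
    if other_allele is None:
        ea, oa = variant.effect_allele, variant.other_allele
    else:
        ea, oa = variant, other_allele
    return COMPLEMENT[ea] == oa


@dataclass
class HarmonizedSet:
    """Exposure and outcome effects aligned to a common effect allele.

    ``bx``/``sx`` are (n_snps, n_exposures) arrays of exposure betas and
    standard errors; ``by``/``sy`` are the outcome beta and SE vectors.
    ``meta`` carries variant_id, chromosome, position and the shared
    effect/other allele per retained row.  ``exclusions`` lists
    (variant_id, reason) pairs for shared variants that could not be
    harmonized; retained rows and exclusions partition the shared-variant
    set exactly.
    """

    exposure_ids: list[str]
    outcome_id: str
    meta: pd.DataFrame = field(repr=False)
    bx: np.ndarray = field(repr=False)
    sx: np.ndarray = field(repr=False)
    by: np.ndarray = field(repr=False)
    sy: np.ndarray = field(repr=False)
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bx = np.atleast_2d(np.asarray(self.bx, dtype=float))
        self.sx = np.atleast_2d(np.asarray(self.sx, dtype=float))
        if self.bx.shape[0] == 1 and len(self.by) != 1:
            self.bx = self.bx.T
        if self.sx.shape != self.bx.shape and self.sx.T.shape == self.bx.shape:
            self.sx = self.sx.T
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        n = len(self.by)
        if self.bx.shape != (n, len(self.exposure_ids)) or self.sx.shape != self.bx.shape:
            raise DataError("bx/sx shape does not match (n_snps, n_exposures)")
        if len(self.sy) != n or len(self.meta) != n:
            raise DataError("by/sy/meta lengths disagree")
        if n and ((self.sx <= 0).any() or (self.sy <= 0).any()):
            raise DataError("standard errors must be positive")
        retained = set(self.meta["variant_id"])
        if retained & {v for v, _ in self.exclusions}:
            raise DataError("a variant appears in both rows and exclusions")

    @property
    def n_snps(self) -> int:
        return len(self.by)

    @property
    def n_exposures(self) -> int:
        return len(self.exposure_ids)

    @property
    def variant_ids(self) -> list[str]:
        return self.meta["variant_id"].tolist()

    @classmethod
    def from_arrays(cls, bx, sx, by, sy, exposure_ids: Optional[Sequence[str]] = None,
                    outcome_id: str = "outcome",
                    variant_ids: Optional[Sequence[str]] = None) -> "HarmonizedSet":
        """Build a set directly from effect arrays (simulation / testing path)."""
        bx = np.atleast_2d(np.asarray(bx, dtype=float))
        if bx.shape[0] == 1 and len(np.atleast_1d(by)) != 1:
            bx = bx.T
        n, k = bx.shape
        if exposure_ids is None:
            exposure_ids = [f"exposure{i + 1}" for i in range(k)]
        if variant_ids is None:
            variant_ids = [f"rs{i + 1}" for i in range(n)]
        meta = pd.DataFrame({
            "variant_id": list(variant_ids),
            "chromosome": ["1"] * n,
            "position": np.arange(1, n + 1) * 1_000_000,
            "effect_allele": ["A"] * n,
            "other_allele": ["G"] * n,
        })
        return cls(list(exposure_ids), outcome_id, meta, bx, np.asarray(sx, dtype=float),
                   by, sy)

    def subset(self, mask: np.ndarray) -> "HarmonizedSet":
        """Row-subset by boolean mask; exclusions are carried over unchanged."""
        mask = np.asarray(mask, dtype=bool)
        return HarmonizedSet(
            list(self.exposure_ids), self.outcome_id,
            self.meta[mask].reset_index(drop=True),
            self.bx[mask], self.sx[mask], self.by[mask], self.sy[mask],
            list(self.exclusions),
        )

    def to_dataframe(self) -> pd.DataFrame:
        out = self.meta.copy()
        for k, eid in enumerate(self.exposure_ids):
            out[f"beta_{eid}"] = self.bx[:, k]
            out[f"se_{eid}"] = self.sx[:, k]
        out[f"beta_{self.outcome_id}"] = self.by
        out[f"se_{self.outcome_id}"] = self.sy
        return out

    def exclusion_report(self) -> pd.DataFrame:
        rows = [{"variant_id": v, "action": "excluded", "reason": r}
                for v, r in self.exclusions]
        rows += [{"variant_id": v, "action": "retained", "reason": ""}
                 for v in self.variant_ids]
        return pd.DataFrame(rows, columns=["variant_id", "action", "reason"])

    def _as_sumstats(self, beta: np.ndarray, se: np.ndarray, trait_id: str) -> SummaryStats:
        z = np.abs(beta / se)
        table = self.meta.copy()
        table["eaf"] = np.nan
        table["beta"] = beta
        table["se"] = se
        table["pvalue"] = 2.0 * stats.norm.sf(z)
        table["n"] = np.nan
        return SummaryStats(trait_id, table)

    def exposure_sumstats(self, k: int = 0) -> SummaryStats:
        """Reconstruct the k-th exposure as SummaryStats on the shared allele."""
        return self._as_sumstats(self.bx[:, k], self.sx[:, k], self.exposure_ids[k])

    def outcome_sumstats(self) -> SummaryStats:
        return self._as_sumstats(self.by, self.sy, self.outcome_id)


def _alignment(ref_ea: str, ref_oa: str, ea: str, oa: str) -> Optional[tuple[bool, bool]]:
    """How a record's alleles map onto the reference pair.

    Returns (flip_sign, complemented) or None when the pairs are
    irreconcilable.  For palindromic reference pairs the complemented
    mapping is indistinguishable from a swap, so the caller must resolve
    orientation by frequency (or exclude).
    """
    if (ea, oa) == (ref_ea, ref_oa):
        return (False, False)
    if (ea, oa) == (ref_oa, ref_ea):
        return (True, False)
    cea, coa = COMPLEMENT[ea], COMPLEMENT[oa]
    if (cea, coa) == (ref_ea, ref_oa):
        return (False, True)
    if (cea, coa) == (ref_oa, ref_ea):
        return (True, True)
    return None


def harmonize(exposures: Sequence[SummaryStats] | SummaryStats, outcome: SummaryStats,
              eaf_available: bool = False, eaf_window: float = 0.08) -> HarmonizedSet:
    """Align one or more exposures and an outcome to a shared effect allele.

    The first exposure's effect allele is the reference; additional
    exposures and the outcome are mapped onto it.  Per shared variant:
    identical alleles are copied; swapped alleles negate the beta (and
    mirror the eaf); complementary-strand representations are mapped first
    and then copied/negated.  Palindromic variants are excluded with reason
    ``"palindromic"`` unless ``eaf_available`` and both frequencies lie
    outside ``0.5 ± eaf_window``, in which case orientation follows the
    minor allele.  Irreconcilable pairs are excluded with reason
    ``"allele_mismatch"``.

    Raises :class:`DataError` when no variant is shared by all datasets.
    """
    if isinstance(exposures, SummaryStats):
        exposures = [exposures]
    exposures = list(exposures)
    datasets = exposures + [outcome]
    shared = set(datasets[0].variant_ids)
    for ds in datasets[1:]:
        shared &= set(ds.variant_ids)
    if not shared:
        raise DataError(
            f"no shared variants between {[d.trait_id for d in exposures]} and {outcome.trait_id}"
        )
    ref = exposures[0]
    order = [v for v in ref.variant_ids if v in shared]
    lookups = [ds.table.set_index("variant_id") for ds in datasets]

    meta_rows, bx_rows, sx_rows, by_list, sy_list = [], [], [], [], []
    exclusions: list[tuple[str, str]] = []
    for vid in order:
        ref_rec = lookups[0].loc[vid]
        ref_ea, ref_oa = ref_rec["effect_allele"], ref_rec["other_allele"]
        palindromic = classify_palindromic(ref_ea, ref_oa)
        betas, ses = [], []
        failure: Optional[str] = None
        for k, lk in enumerate(lookups):
            rec = lk.loc[vid]
            ea, oa = rec["effect_allele"], rec["other_allele"]
            mapping = _alignment(ref_ea, ref_oa, ea, oa)
            if mapping is None:
                failure = "allele_mismatch"
                break
            flip, _comp = mapping
            eaf = rec.get("eaf", np.nan)
            if palindromic and k > 0:
                ref_eaf = ref_rec.get("eaf", np.nan)
                flip = _orient_palindromic(ref_ea, ref_eaf, ea, eaf,
                                           eaf_available, eaf_window)
                if flip is None:
                    failure = "palindromic"
                    break
            betas.append(-rec["beta"] if flip else rec["beta"])
            ses.append(rec["se"])
        if failure is not None:
            exclusions.append((vid, failure))
            continue
        meta_rows.append({
            "variant_id": vid,
            "chromosome": ref_rec["chromosome"],
            "position": int(ref_rec["position"]),
            "effect_allele": ref_ea,
            "other_allele": ref_oa,
        })
        bx_rows.append(betas[:-1])
        sx_rows.append(ses[:-1])
        by_list.append(betas[-1])
        sy_list.append(ses[-1])

    meta = pd.DataFrame(meta_rows, columns=_META_COLUMNS)
    k = len(exposures)
    bx = np.asarray(bx_rows, dtype=float).reshape(len(meta_rows), k)
    sx = np.asarray(sx_rows, dtype=float).reshape(len(meta_rows), k)
    return HarmonizedSet(
        [e.trait_id for e in exposures], outcome.trait_id, meta,
        bx, sx, np.asarray(by_list, dtype=float), np.asarray(sy_list, dtype=float),
        exclusions,
    )


def _orient_palindromic(ref_ea: str, ref_eaf: float, ea: str, eaf: float,
                        eaf_available: bool, eaf_window: float) -> Optional[bool]:
    """Resolve a palindromic variant's orientation by minor-allele matching.

    Returns the sign-flip decision, or None when frequencies are missing or
    inside the ambiguity window (variant must then be excluded).
    """
    if not eaf_available:
        return None
    if ref_eaf is None or eaf is None or np.isnan(ref_eaf) or np.isnan(eaf):
        return None
    lo, hi = 0.5 - eaf_window, 0.5 + eaf_window
    if lo <= ref_eaf <= hi or lo <= eaf <= hi:
        return None
    # frequency this record implies for the reference effect allele
    f = eaf if ea == ref_ea else 1.0 - eaf
    return (f < 0.5) != (ref_eaf < 0.5)
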