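"""Reading, validating, and harmonizing GWAS summary statistics.

Two-sample MR needs the per-SNP exposure and outcome effects expressed with
respect to the *same* effect allele.  Summary-statistics files from different
consortia disagree on column names and on which allele the beta refers to, so
this module (a) adapts arbitrary headers through a ``column_map`` and (b)
re-orients outcome effects onto the exposure's effect allele, handling swapped
alleles, strand flips, and ambiguous palindromic variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import (
    ConfigurationError,
    HarmonizationError,
    NoSharedInstrumentsError,
    ValidationError,
)

__all__ = [
    "VariantAssociation",
    "HarmonizedInstrument",
    "RejectedRow",
    "read_sumstats",
    "harmonize",
    "apply_proxies",
    "write_harmonized",
    "read_harmonized",
    "HARMONIZED_COLUMNS",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical field -> default column name in input files
CANONICAL_COLUMNS = {
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}

MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")

HARMONIZED_COLUMNS = (
    "snp_id",
    "bx",
    "sex",
    "px",
    "by",
    "sey",
    "py",
    "eaf_x",
    "n_x",
    "n_y",
)


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary-level association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele``; for binary traits
    it is on the log-odds scale.  ``eaf`` is the effect-allele frequency and
    may be ``None`` when the source file does not report it (such records are
    retained but flagged and excluded from variance-explained computations).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str = ""
    pos: int = 0
    eaf: float | None = None
    n: int = 0

    def __post_init__(self):
        if self.se <= 0 or not math.isfinite(self.se):
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.snp_id}: pval must be in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.snp_id}: eaf must be in [0, 1], got {self.eaf}")
        ea, oa = self.effect_allele.upper(), self.other_allele.upper()
        if ea == oa:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical ({ea})")
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: beta is not finite")

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``; None when eaf is missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G variants, whose strand cannot be read off the alleles."""
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP's exposure and outcome effects on the same effect allele."""

    snp_id: str
    bx: float
    sex: float
    by: float
    sey: float
    px: float = 1.0
    py: float = 1.0
    eaf_x: float | None = None
    n_x: int = 0
    n_y: int = 0

    def __post_init__(self):
        if self.sex <= 0 or self.sey <= 0:
            raise ValidationError(f"{self.snp_id}: harmonized SEs must be > 0")


@dataclass(frozen=True)
class RejectedRow:
    """Provenance of a rejected input row or a dropped SNP, with a reason."""

    snp_id: str
    reason: str
    line: int | None = None


def _coerce_float(value, field_name: str, line: int, snp: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"line {line}: unparseable {field_name} {value!r} for SNP {snp}"
        ) from None


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
    return_rejects: bool = False,
):
    """Read a delimited summary-statistics file into validated records.

    Parameters
    ----------
    path:
        Tab- or comma-delimited text file with a header row.
    column_map:
        Mapping from canonical field name (``snp_id``, ``effect_allele``,
        ``other_allele``, ``beta``, ``se``, ``pval``, and optionally ``chrom``,
        ``pos``, ``eaf``, ``n``) to the column name used in the file.  Fields
        absent from the map fall back to the canonical names themselves.
    sep:
        Field separator; autodetected (tab, then comma) when None.
    return_rejects:
        When True, also return the list of :class:`RejectedRow` describing
        rows that violated an invariant (with 1-based data line numbers).

    Raises
    ------
    ConfigurationError
        If a mandatory column is missing from the file, naming the column.
    """
    cmap = dict(CANONICAL_COLUMNS)
    if column_map:
        cmap.update(column_map)

    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str)

    for fld in MANDATORY_FIELDS:
        if cmap[fld] not in df.columns:
            raise ConfigurationError(
                f"mandatory column {cmap[fld]!r} (field {fld!r}) missing from {path}"
            )

    has = {f: cmap[f] in df.columns for f in CANONICAL_COLUMNS}
    records: list[VariantAssociation] = []
    rejects: list[RejectedRow] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        snp = str(row[cmap["snp_id"]])
        try:
            eaf_raw = row[cmap["eaf"]] if has["eaf"] else None
            eaf = None
            if eaf_raw is not None and str(eaf_raw).upper() not in ("", "NA", "NAN", "."):
                eaf = _coerce_float(eaf_raw, "eaf", i, snp)
            rec = VariantAssociation(
                snp_id=snp,
                chrom=str(row[cmap["chrom"]]) if has["chrom"] else "",
                pos=int(float(row[cmap["pos"]])) if has["pos"] else 0,
                effect_allele=str(row[cmap["effect_allele"]]),
                other_allele=str(row[cmap["other_allele"]]),
                eaf=eaf,
                beta=_coerce_float(row[cmap["beta"]], "beta", i, snp),
                se=_coerce_float(row[cmap["se"]], "se", i, snp),
                pval=_coerce_float(row[cmap["pval"]], "pval", i, snp),
                n=int(float(row[cmap["n"]])) if has["n"] else 0,
            )
        except ValidationError as err:
            rejects.append(RejectedRow(snp_id=snp, reason=str(err), line=i))
            continue
        records.append(rec)

    if return_rejects:
        return records, rejects
    return records


def apply_proxies(
    outcome: Sequence[VariantAssociation],
    proxy_map: Mapping[str, str],
) -> list[VariantAssociation]:
    """Relabel outcome SNPs through a user-supplied proxy table.

    ``proxy_map`` maps a query SNP id (present in the exposure but absent from
    the outcome) to the id of a proxy SNP present in the outcome; the supplier
    is responsible for the LD requirement (conventionally r^2 >= 0.8).  The
    proxy's association is re-keyed to the query id so downstream pairing by
    snp_id works unchanged.
    """
    inverse = {proxy: query for query, proxy in proxy_map.items()}
    out = []
    for rec in outcome:
        if rec.snp_id in inverse:
            rec = replace(rec, snp_id=inverse[rec.snp_id])
        out.append(rec)
    return out


def _alleles_equal(a: VariantAssociation, b: VariantAssociation) -> bool:
    return a.effect_allele == b.effect_allele and a.other_allele == b.other_allele


def _alleles_swapped(a: VariantAssociation, b: VariantAssociation) -> bool:
    return a.effect_allele == b.other_allele and a.other_allele == b.effect_allele


def _complemented(rec: VariantAssociation) -> VariantAssociation | None:
    try:
        return replace(
            rec,
            effect_allele=_COMPLEMENT[rec.effect_allele],
            other_allele=_COMPLEMENT[rec.other_allele],
        )
    except KeyError:
        return None


def _flip(rec: VariantAssociation) -> VariantAssociation:
    """Swap allele labels, negating beta and complementing eaf."""
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def harmonize(
    exposure: Sequence[VariantAssociation],
    outcome: Sequence[VariantAssociation],
    palindrome_policy: str = "drop_ambiguous",
    ambiguity_band: float = 0.08,
    *,
    proxy_map: Mapping[str, str] | None = None,
    return_dropped: bool = False,
):
    """Align outcome effects onto each exposure SNP's effect allele.

    For each SNP shared between the two tables: if the outcome reports the
    same allele pair, its effect is copied; if the alleles are swapped, the
    outcome beta's sign is flipped (and eaf complemented); if only the strand
    complement matches (directly or swapped), the outcome record is
    complemented first.  Palindromic variants (A/T, C/G) whose strand cannot
    be resolved from alleles are dropped when their exposure eaf lies within
    ``ambiguity_band`` of 0.5 (policy ``"drop_ambiguous"``), or aligned by
    allele frequency otherwise (policy ``"infer_by_frequency"``); outside the
    band, frequency alignment is always attempted, and palindromes with a
    missing eaf on either side are dropped as unresolvable.

    Parameters
    ----------
    palindrome_policy:
        ``"drop_ambiguous"`` (default) or ``"infer_by_frequency"``.
    ambiguity_band:
        Half-width of the eaf window around 0.5 inside which a palindrome is
        considered ambiguous; the default 0.08 drops eaf in [0.42, 0.58].
    proxy_map:
        Optional query-SNP -> proxy-SNP substitution table applied to the
        outcome before pairing (see :func:`apply_proxies`).
    return_dropped:
        When True, also return a list of :class:`RejectedRow` explaining every
        shared SNP that was dropped.

    Raises
    ------
    NoSharedInstrumentsError
        If both inputs are non-empty but share no SNP id.
    HarmonizationError
        If either input is empty.
    """
    if palindrome_policy not in ("drop_ambiguous", "infer_by_frequency"):
        raise ConfigurationError(f"unknown palindrome_policy {palindrome_policy!r}")
    if not exposure or not outcome:
        raise HarmonizationError("empty exposure or outcome input")
    if proxy_map:
        outcome = apply_proxies(outcome, proxy_map)

    out_by_id = {rec.snp_id: rec for rec in outcome}
    shared = [rec for rec in exposure if rec.snp_id in out_by_id]
    if not shared:
        raise NoSharedInstrumentsError(
            "no shared instruments between exposure and outcome"
        )

    harmonized: list[HarmonizedInstrument] = []
    dropped: list[RejectedRow] = []
    for exp in shared:
        out = out_by_id[exp.snp_id]
        if exp.is_palindromic:
            res = _harmonize_palindrome(exp, out, palindrome_policy, ambiguity_band)
            if isinstance(res, str):
                dropped.append(RejectedRow(snp_id=exp.snp_id, reason=res))
                continue
            aligned = res
        else:
            aligned = _orient(exp, out)
            if aligned is None:
                dropped.append(
                    RejectedRow(
                        snp_id=exp.snp_id,
                        reason="incompatible alleles "
                        f"{exp.effect_allele}/{exp.other_allele} vs "
                        f"{out.effect_allele}/{out.other_allele}",
                    )
                )
                continue
        harmonized.append(
            HarmonizedInstrument(
                snp_id=exp.snp_id,
                bx=exp.beta,
                sex=exp.se,
                px=exp.pval,
                by=aligned.beta,
                sey=aligned.se,
                py=aligned.pval,
                eaf_x=exp.eaf,
                n_x=exp.n,
                n_y=aligned.n,
            )
        )
    if return_dropped:
        return harmonized, dropped
    return harmonized


def _orient(exp: VariantAssociation, out: VariantAssociation) -> VariantAssociation | None:
    """Return the outcome record expressed on exp's effect allele, or None."""
    if _alleles_equal(exp, out):
        return out
    if _alleles_swapped(exp, out):
        return _flip(out)
    # strand complement only after direct and swapped matching both fail
    comp = _complemented(out)
    if comp is not None:
        if _alleles_equal(exp, comp):
            return comp
        if _alleles_swapped(exp, comp):
            return _flip(comp)
    return None


def _harmonize_palindrome(
    exp: VariantAssociation,
    out: VariantAssociation,
    policy: str,
    band: float,
):
    """Resolve an A/T or C/G variant; returns an aligned record or a drop reason."""
    if not out.is_palindromic:
        return "palindrome with incompatible outcome alleles"
    aligned = _orient(exp, out)
    if aligned is None:
        return "palindrome with incompatible outcome alleles"
    ambiguous = exp.eaf is not None and abs(exp.eaf - 0.5) <= band
    if ambiguous and policy == "drop_ambiguous":
        return "ambiguous palindrome"
    if exp.eaf is None or aligned.eaf is None:
        return "palindrome with missing allele frequency"
    # allele labels carry no strand information for a palindrome, so the
    # label-based orientation is checked against allele frequency: if the
    # aligned outcome eaf sits on the opposite side of 0.5, the strands
    # disagree and the orientation is flipped.
    if (exp.eaf < 0.5) != (aligned.eaf < 0.5):
        aligned = _flip(aligned)
    return aligned


def to_frame(insts: Iterable[HarmonizedInstrument]) -> pd.DataFrame:
    """Harmonized instruments as a DataFrame with the canonical column order."""
    rows = [
        {
            "snp_id": h.snp_id,
            "bx": h.bx,
            "sex": h.sex,
            "px": h.px,
            "by": h.by,
            "sey": h.sey,
            "py": h.py,
            "eaf_x": h.eaf_x,
            "n_x": h.n_x,
            "n_y": h.n_y,
        }
        for h in insts
    ]
    return pd.DataFrame(rows, columns=list(HARMONIZED_COLUMNS))


def write_harmonized(insts: Iterable[HarmonizedInstrument], path) -> None:
    """Write instruments as tab-delimited text with the canonical header."""
    to_frame(insts).to_csv(path, sep="\t", index=False)


def read_harmonized(path) -> list[HarmonizedInstrument]:
    df = pd.read_csv(path, sep="\t")
    missing = set(HARMONIZED_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"harmonized table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        eaf = getattr(row, "eaf_x")
        out.append(
            HarmonizedInstrument(
                snp_id=str(row.snp_id),
                bx=float(row.bx),
                sex=float(row.sex),
                px=float(row.px),
                by=float(row.by),
                sey=float(row.sey),
                py=float(row.py),
                eaf_x=None if pd.isna(eaf) else float(eaf),
                n_x=int(row.n_x),
                n_y=int(row.n_y),
            )
        )
    return out
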