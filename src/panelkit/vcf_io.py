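"""Readers and writers for the file formats the pipeline consumes.

All coordinates are VCF-style 1-based inclusive positions; no 0-based
conversion happens anywhere in the package.  Site identity is the exact
uppercased ``(chrom, pos, ref, alt)`` tuple — no strand flipping or allele
swapping is ever attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING = -1  # genotype-code sentinel used in every matrix layer

#: INFO tags accepted as the per-site imputation information score, in the
#: order they are tried when ``info_field`` is left at its default.  Beagle
#: 5.x writes DR2; other engines write INFO or R2.
INFO_SCORE_TAGS = ("DR2", "INFO", "R2")


class VcfParseError(ValueError):
    """Malformed VCF header or record (message carries the record number)."""


class UnsupportedPloidyError(ValueError):
    """A GT call with ploidy other than 2 was encountered."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSite:
    """One variant record: biallelic, or multiallelic before splitting.

    ``ac``/``af`` carry one entry per alternate allele, mirroring the VCF
    Number=A convention.  ``af`` should equal ``ac/an`` whenever ``an`` > 0.
    """

    chrom: str
    pos: int
    id: str
    ref: str
    alts: tuple[str, ...]
    ac: tuple[int, ...] = ()
    an: int = 0
    af: tuple[float, ...] = ()
    excess_het: Optional[float] = None
    filter: str = "PASS"
    info_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.alts:
            raise ValueError("site needs at least one alternate allele")
        for alt in self.alts:
            if alt == self.ref:
                raise ValueError(f"ref == alt ({alt}) at {self.chrom}:{self.pos}")
        if self.ac and self.an:
            for c in self.ac:
                if not 0 <= c <= self.an:
                    raise ValueError(f"AC {c} outside [0, AN={self.an}]")

    @property
    def alt(self) -> str:
        """Single alternate allele; raises on multiallelic records."""
        if len(self.alts) != 1:
            raise ValueError(f"site {self.chrom}:{self.pos} is multiallelic")
        return self.alts[0]

    @property
    def af1(self) -> Optional[float]:
        """First-alt allele frequency, or None when unannotated."""
        return self.af[0] if self.af else None

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Exact-match identity key (biallelic sites only)."""
        return (self.chrom, self.pos, self.ref.upper(), self.alt.upper())

    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    def with_counts(self, ac: Sequence[int], an: int) -> "VariantSite":
        af = tuple(c / an if an > 0 else math.nan for c in ac)
        return replace(self, ac=tuple(int(c) for c in ac), an=int(an), af=af)


@dataclass
class GenotypeMatrix:
    """samples × sites hard-call codes with optional parallel layers.

    ``codes[i, j]`` counts alternate alleles carried by sample *i* at site
    *j*: 0 hom-ref, 1 het, 2 hom-alt, :data:`MISSING` for no-calls.  For
    multiallelic records the code counts *any* non-reference allele; the raw
    allele-index pairs are kept in ``allele_pairs`` so that
    :func:`panelkit.panel_qc.split_multiallelic` can recover per-alt doses.
    """

    codes: np.ndarray
    samples: list[str]
    gq: Optional[np.ndarray] = None
    dosage: Optional[np.ndarray] = None
    allele_pairs: Optional[np.ndarray] = None  # (n_samples, n_sites, 2)
    phased: bool = False

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D samples × sites array")
        if len(self.samples) != self.codes.shape[0]:
            raise ValueError(
                f"{len(self.samples)} sample ids for {self.codes.shape[0]} rows"
            )
        for name in ("gq", "dosage"):
            layer = getattr(self, name)
            if layer is not None and layer.shape != self.codes.shape:
                raise ValueError(f"{name} layer shape {layer.shape} != codes "
                                 f"shape {self.codes.shape}")
        if self.allele_pairs is not None and (
            self.allele_pairs.shape != self.codes.shape + (2,)
        ):
            raise ValueError("allele_pairs must be (n_samples, n_sites, 2)")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def column(self, j: int) -> np.ndarray:
        return self.codes[:, j]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            codes=self.codes.copy(),
            samples=list(self.samples),
            gq=None if self.gq is None else self.gq.copy(),
            dosage=None if self.dosage is None else self.dosage.copy(),
            allele_pairs=(None if self.allele_pairs is None
                          else self.allele_pairs.copy()),
            phased=self.phased,
        )


@dataclass(frozen=True)
class KinshipPair:
    """One unordered sample pair with its KING kinship coefficient."""

    sample_a: str
    sample_b: str
    kinship: float

    def __post_init__(self) -> None:
        if self.sample_a == self.sample_b:
            raise ValueError(f"self-pair for sample {self.sample_a}")
        if not -1.0 <= self.kinship <= 0.5:
            raise ValueError(f"kinship {self.kinship} outside [-1, 0.5]")

    @property
    def key(self) -> tuple[str, str]:
        a, b = sorted((self.sample_a, self.sample_b))
        return (a, b)


@dataclass(frozen=True)
class AssocRecord:
    """Per-SNP association summary (one row of a GWAS results table)."""

    chrom: str
    pos: int
    id: str
    beta: float
    se: float
    p: float
    maf: float = math.nan
    hwe_p: float = math.nan
    missing_rate: float = math.nan


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _info_float(variant, tag: str) -> Optional[float]:
    val = variant.INFO.get(tag)
    if val is None:
        return None
    if isinstance(val, tuple):
        val = val[0]
    return float(val)


def read_genotype_vcf(
    path: str | Path,
    info_field: Optional[str] = None,
) -> tuple[list[VariantSite], GenotypeMatrix]:
    """Read a diploid VCF into sites plus a genotype matrix.

    Genotype codes count non-reference alleles; ``0|1`` and ``0/1`` both map
    to 1, and half-calls or ``./.`` map to :data:`MISSING`.  Multiallelic
    records are retained whole (all alts), with raw allele-index pairs stored
    for downstream splitting.

    Parameters
    ----------
    path
        VCF v4.x file, plain or bgzipped, with GT and optional GQ/DS fields.
    info_field
        INFO tag to read as the imputation information score.  Default:
        try ``DR2``, then ``INFO``, then ``R2``.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib raises bare OSError/Exception
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc

    samples = list(vcf.samples)
    tags = (info_field,) if info_field else INFO_SCORE_TAGS

    sites: list[VariantSite] = []
    code_cols: list[np.ndarray] = []
    gq_cols: list[np.ndarray] = []
    ds_cols: list[np.ndarray] = []
    pair_cols: list[np.ndarray] = []
    any_gq = any_ds = False
    phased = False

    for rec_no, v in enumerate(vcf, start=1):
        try:
            gts = np.asarray(v.genotype.array(), dtype=np.int16)
        except Exception as exc:
            raise VcfParseError(
                f"{path}: record {rec_no} ({v.CHROM}:{v.POS}): bad GT: {exc}"
            ) from exc
        if gts.shape[1] != 3:
            raise UnsupportedPloidyError(
                f"{path}: record {rec_no} ({v.CHROM}:{v.POS}): "
                f"ploidy {gts.shape[1] - 1} unsupported (diploid only)"
            )
        alleles = gts[:, :2]
        phased = phased or bool(np.any(gts[:, 2] > 0))

        missing = np.any(alleles < 0, axis=1)
        codes = np.sum(alleles > 0, axis=1).astype(np.int8)
        codes[missing] = MISSING
        pairs = alleles.astype(np.int8)
        pairs[missing] = MISSING

        alts = tuple(v.ALT)
        if not alts or alts == (".",):
            alts = ()

        ac_raw = v.INFO.get("AC")
        an_raw = v.INFO.get("AN")
        af_raw = v.INFO.get("AF")
        as_tuple = lambda x: (x,) if not isinstance(x, tuple) else x
        info_score = None
        for tag in tags:
            info_score = _info_float(v, tag)
            if info_score is not None:
                break

        site = VariantSite(
            chrom=v.CHROM,
            pos=v.POS,
            id=v.ID or "",
            ref=v.REF,
            alts=alts if alts else (".",),
            ac=tuple(int(c) for c in as_tuple(ac_raw)) if ac_raw is not None else (),
            an=int(an_raw) if an_raw is not None else 0,
            af=tuple(float(f) for f in as_tuple(af_raw)) if af_raw is not None else (),
            excess_het=_info_float(v, "ExcessHet"),
            filter=v.FILTER or "PASS",
            info_score=info_score,
        )
        sites.append(site)
        code_cols.append(codes)
        pair_cols.append(pairs)

        try:
            gq = v.format("GQ")
        except KeyError:
            gq = None
        if gq is not None:
            any_gq = True
            gq_cols.append(np.where(gq[:, 0] < 0, 0, gq[:, 0]).astype(np.int16))
        else:
            gq_cols.append(np.full(len(samples), -1, dtype=np.int16))
        try:
            ds = v.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            any_ds = True
            ds_cols.append(ds[:, 0].astype(np.float32))
        else:
            ds_cols.append(np.full(len(samples), np.nan, dtype=np.float32))

    n_sites = len(sites)
    codes = (np.stack(code_cols, axis=1) if n_sites
             else np.empty((len(samples), 0), dtype=np.int8))
    pairs = (np.stack(pair_cols, axis=1) if n_sites
             else np.empty((len(samples), 0, 2), dtype=np.int8))
    matrix = GenotypeMatrix(
        codes=codes,
        samples=samples,
        gq=np.stack(gq_cols, axis=1) if any_gq else None,
        dosage=np.stack(ds_cols, axis=1) if any_ds else None,
        allele_pairs=pairs,
        phased=phased,
    )
    return sites, matrix


# ---------------------------------------------------------------------------
# VCF writing
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">',
    '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total called alleles">',
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">',
    '##INFO=<ID=ExcessHet,Number=1,Type=Float,Description="Phred-scaled '
    'heterozygote-excess probability">',
    '##INFO=<ID=DR2,Number=1,Type=Float,Description="Imputation information score">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">',
]


def _fmt_float(x: float) -> str:
    s = f"{x:.6g}"
    return s


def write_genotype_vcf(
    sites: Sequence[VariantSite],
    genotypes: GenotypeMatrix,
    path: str | Path,
    recompute_counts: bool = False,
) -> None:
    """Write sites + genotypes as a plain-text VCF v4.2 file.

    The output re-reads (via :func:`read_genotype_vcf`) to the same sites and
    matrix on all supported fields.  With ``recompute_counts`` the AC/AN/AF
    annotations are rederived from the genotype codes before writing.
    """
    if len(sites) != genotypes.n_sites:
        raise ValueError(
            f"{len(sites)} sites but matrix has {genotypes.n_sites} columns"
        )
    sep = "|" if genotypes.phased else "/"
    has_gq = genotypes.gq is not None
    has_ds = genotypes.dosage is not None
    fmt = "GT" + (":GQ" if has_gq else "") + (":DS" if has_ds else "")

    with open(path, "w") as fh:
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        for chrom in dict.fromkeys(s.chrom for s in sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        for j, site in enumerate(sites):
            col = genotypes.codes[:, j]
            if recompute_counts:
                site = site.with_counts(*_counts_from_codes(col))
            info = []
            if site.ac:
                info.append("AC=" + ",".join(str(c) for c in site.ac))
            if site.an:
                info.append(f"AN={site.an}")
            if site.af:
                info.append("AF=" + ",".join(_fmt_float(f) for f in site.af))
            if site.excess_het is not None:
                info.append(f"ExcessHet={_fmt_float(site.excess_het)}")
            if site.info_score is not None:
                info.append(f"DR2={_fmt_float(site.info_score)}")
            fields = [
                site.chrom, str(site.pos), site.id or ".", site.ref,
                ",".join(site.alts), ".", site.filter or "PASS",
                ";".join(info) or ".", fmt,
            ]
            pairs = (genotypes.allele_pairs[:, j]
                     if genotypes.allele_pairs is not None else None)
            for i in range(genotypes.n_samples):
                c = col[i]
                if c == MISSING:
                    gt = "." + sep + "."
                elif pairs is not None and pairs[i, 0] != MISSING:
                    gt = f"{pairs[i, 0]}{sep}{pairs[i, 1]}"
                else:
                    gt = {0: f"0{sep}0", 1: f"0{sep}1", 2: f"1{sep}1"}[int(c)]
                parts = [gt]
                if has_gq:
                    parts.append(str(int(genotypes.gq[i, j])))
                if has_ds:
                    d = genotypes.dosage[i, j]
                    parts.append("." if np.isnan(d) else f"{d:.4f}")
                fields.append(":".join(parts))
            fh.write("\t".join(fields) + "\n")


def _counts_from_codes(col: np.ndarray) -> tuple[tuple[int], int]:
    ok = col != MISSING
    ac = int(col[ok].sum())
    an = int(2 * ok.sum())
    return (ac,), an


# ---------------------------------------------------------------------------
# kinship tables (KING .kin0 dialect)
# ---------------------------------------------------------------------------

def read_kinship_table(path: str | Path) -> list[KinshipPair]:
    """Read a whitespace-delimited KING-style kinship table.

    Columns are located by header names containing ``ID1``, ``ID2`` and
    ``Kinship`` (case-insensitive).  Duplicate unordered pairs collapse to a
    single entry keeping the maximum kinship.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    c1 = next((cols[l] for l in cols if "id1" in l), None)
    c2 = next((cols[l] for l in cols if "id2" in l), None)
    ck = next((cols[l] for l in cols if "kinship" in l), None)
    if c1 is None or c2 is None or ck is None:
        raise ValueError(
            f"{path}: need ID1/ID2/Kinship columns; found {list(df.columns)}"
        )

    best: dict[tuple[str, str], KinshipPair] = {}
    for a, b, k in zip(df[c1], df[c2], df[ck].astype(float)):
        pair = KinshipPair(str(a), str(b), float(k))
        prev = best.get(pair.key)
        if prev is None or pair.kinship > prev.kinship:
            best[pair.key] = pair
    return list(best.values())


def write_kinship_table(pairs: Iterable[KinshipPair], path: str | Path) -> None:
    rows = [(p.sample_a, p.sample_b, p.kinship) for p in pairs]
    pd.DataFrame(rows, columns=["ID1", "ID2", "Kinship"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# association tables
# ---------------------------------------------------------------------------

_ASSOC_COLS = {
    "CHR": "chrom", "POS": "pos", "ID": "id", "MAF": "maf", "HWE_P": "hwe_p",
    "MISS": "missing_rate", "BETA": "beta", "SE": "se", "P": "p",
}


def read_assoc_table(path: str | Path) -> list[AssocRecord]:
    """Read a delimited GWAS results table into :class:`AssocRecord` rows.

    P-values (and all numeric fields) parse as floats, scientific notation
    included.  Required columns: CHR POS ID BETA SE P; MAF/HWE_P/MISS are
    optional.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"CHR": str, "ID": str})
    missing = {"CHR", "POS", "ID", "BETA", "SE", "P"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not pd.api.types.is_numeric_dtype(df["P"]):
        bad = df.loc[pd.to_numeric(df["P"], errors="coerce").isna(), "P"]
        raise ValueError(f"{path}: non-numeric P values, e.g. {bad.iloc[0]!r}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(AssocRecord(
            chrom=str(d["CHR"]), pos=int(d["POS"]), id=str(d["ID"]),
            beta=float(d["BETA"]), se=float(d["SE"]), p=float(d["P"]),
            maf=float(d.get("MAF", math.nan)),
            hwe_p=float(d.get("HWE_P", math.nan)),
            missing_rate=float(d.get("MISS", math.nan)),
        ))
    return records


def write_assoc_table(records: Sequence[AssocRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.chrom, r.pos, r.id, r.maf, r.hwe_p, r.missing_rate,
          r.beta, r.se, r.p) for r in records],
        columns=["CHR", "POS", "ID", "MAF", "HWE_P", "MISS", "BETA", "SE", "P"],
    )
    # NA sentinel keeps whitespace-delimited columns aligned for NaN fields
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")
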