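"""Case-parent trio data model, readers/writers and cohort summaries.

A :class:`TrioDataset` holds one affected child plus both parents per trio,
genotyped at a shared SNP list, together with a binary maternal exposure and a
self-reported ancestry (SRA) label.  Genotypes are stored as minor-allele
counts (0/1/2, ``-1`` for missing); the minor allele is defined from the
pooled *parental* allele frequency, because affected children are ascertained
and the parents approximate the source population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: fixed column order of per-SNP results tables (Tables 3-4 style)
RESULT_COLUMNS = [
    "snp_id",
    "n_informative",
    "p_unadj_1df",
    "p_sra_2df",
    "p_eegm_2df",
    "exp_bGE_sra",
    "exp_bGE_sra_lo",
    "exp_bGE_sra_hi",
    "exp_bGE_plus_sra",
    "exp_bGE_plus_sra_lo",
    "exp_bGE_plus_sra_hi",
    "flags",
]


class TrioDataError(ValueError):
    """Raised on malformed trio input (duplicate ids, bad exposures, ...)."""


@dataclass(frozen=True)
class SnpMeta:
    """Metadata for one biallelic SNP.

    ``minor_allele`` is ``"a"`` or ``"b"`` and names which of
    ``allele_a``/``allele_b`` the genotype codes count.  ``parental_maf`` is
    the pooled parental frequency of that allele.
    """

    snp_id: str
    chrom: str
    pos: int
    allele_a: str
    allele_b: str
    minor_allele: str = "b"
    parental_maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise TrioDataError(f"{self.snp_id}: pos must be 1-based (got {self.pos})")
        if self.allele_a == self.allele_b:
            raise TrioDataError(f"{self.snp_id}: alleles must differ")
        if self.minor_allele not in ("a", "b"):
            raise TrioDataError(f"{self.snp_id}: minor_allele must be 'a' or 'b'")


@dataclass(frozen=True)
class TrioRecord:
    """One trio: per-SNP minor-allele counts for child/mother/father plus
    the binary maternal exposure (peri-conceptual period) and SRA label."""

    trio_id: str
    g_child: np.ndarray
    g_mother: np.ndarray
    g_father: np.ndarray
    exposure: float  # 0.0, 1.0 or nan
    sra_label: str | None
    child_sex: int = 0  # 1 male, 2 female, 0 unknown


def mendelian_consistent(
    g_mother: np.ndarray, g_father: np.ndarray, g_child: np.ndarray
) -> np.ndarray:
    """Elementwise Mendelian consistency of child allele counts given parents.

    Missing (``-1``) entries in any member are treated as consistent (they are
    screened as missing elsewhere).
    """
    gm = np.asarray(g_mother)
    gf = np.asarray(g_father)
    gc = np.asarray(g_child)
    # transmissible allele count from a parent: 0 -> {0}, 1 -> {0,1}, 2 -> {1}
    m_lo, m_hi = (gm > 1).astype(int), (gm > 0).astype(int)
    f_lo, f_hi = (gf > 1).astype(int), (gf > 0).astype(int)
    ok = (gc >= m_lo + f_lo) & (gc <= m_hi + f_hi)
    return ok | (gm == MISSING) | (gf == MISSING) | (gc == MISSING)


class TrioDataset:
    """Ordered collection of trios over a shared SNP list.

    Genotypes are kept as ``(n_trios, n_snps)`` integer matrices per family
    member; ``-1`` marks missing.  Exposure is a float vector with ``nan``
    for missing, SRA labels an object array with ``None`` for missing.
    """

    def __init__(
        self,
        trio_ids: Sequence[str],
        snps: Sequence[SnpMeta],
        geno_child: np.ndarray,
        geno_mother: np.ndarray,
        geno_father: np.ndarray,
        exposure: np.ndarray,
        sra_label: np.ndarray,
        child_sex: np.ndarray | None = None,
        provenance: str = "",
    ):
        self.trio_ids = list(trio_ids)
        if len(set(self.trio_ids)) != len(self.trio_ids):
            raise TrioDataError("trio ids must be unique")
        self.snps = list(snps)
        n, m = len(self.trio_ids), len(self.snps)
        for name, g in (
            ("geno_child", geno_child),
            ("geno_mother", geno_mother),
            ("geno_father", geno_father),
        ):
            g = np.asarray(g)
            if g.shape != (n, m):
                raise TrioDataError(f"{name} must have shape ({n}, {m})")
        self.geno_child = np.asarray(geno_child, dtype=np.int8)
        self.geno_mother = np.asarray(geno_mother, dtype=np.int8)
        self.geno_father = np.asarray(geno_father, dtype=np.int8)
        self.exposure = np.asarray(exposure, dtype=float)
        self.sra_label = np.asarray(sra_label, dtype=object)
        self.child_sex = (
            np.zeros(n, dtype=np.int8)
            if child_sex is None
            else np.asarray(child_sex, dtype=np.int8)
        )
        self.provenance = provenance

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.trio_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def record(self, i: int) -> TrioRecord:
        return TrioRecord(
            trio_id=self.trio_ids[i],
            g_child=self.geno_child[i].copy(),
            g_mother=self.geno_mother[i].copy(),
            g_father=self.geno_father[i].copy(),
            exposure=float(self.exposure[i]),
            sra_label=self.sra_label[i],
            child_sex=int(self.child_sex[i]),
        )

    def genotypes(self, member: str) -> np.ndarray:
        """Genotype matrix for ``member`` in {'child', 'mother', 'father'}."""
        try:
            return {
                "child": self.geno_child,
                "mother": self.geno_mother,
                "father": self.geno_father,
            }[member]
        except KeyError:
            raise ValueError(f"unknown member {member!r}") from None

    def subset_trios(self, mask: np.ndarray) -> "TrioDataset":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return TrioDataset(
            [self.trio_ids[i] for i in idx],
            self.snps,
            self.geno_child[idx],
            self.geno_mother[idx],
            self.geno_father[idx],
            self.exposure[idx],
            self.sra_label[idx],
            self.child_sex[idx],
            provenance=self.provenance,
        )

    def subset_snps(self, snp_ids: Iterable[str]) -> "TrioDataset":
        idx = [self.snp_index(s) for s in snp_ids]
        return TrioDataset(
            self.trio_ids,
            [self.snps[j] for j in idx],
            self.geno_child[:, idx],
            self.geno_mother[:, idx],
            self.geno_father[:, idx],
            self.exposure,
            self.sra_label,
            self.child_sex,
            provenance=self.provenance,
        )

    @staticmethod
    def _snp_eq(a: SnpMeta, b: SnpMeta) -> bool:
        same_maf = (
            np.isnan(a.parental_maf) and np.isnan(b.parental_maf)
        ) or np.isclose(a.parental_maf, b.parental_maf, atol=1e-12)
        return (
            replace(a, parental_maf=0.0) == replace(b, parental_maf=0.0) and same_maf
        )

    def equals(self, other: "TrioDataset") -> bool:
        return (
            self.trio_ids == other.trio_ids
            and len(self.snps) == len(other.snps)
            and all(self._snp_eq(a, b) for a, b in zip(self.snps, other.snps))
            and np.array_equal(self.geno_child, other.geno_child)
            and np.array_equal(self.geno_mother, other.geno_mother)
            and np.array_equal(self.geno_father, other.geno_father)
            and np.array_equal(np.isnan(self.exposure), np.isnan(other.exposure))
            and np.array_equal(
                np.nan_to_num(self.exposure), np.nan_to_num(other.exposure)
            )
            and all(a == b for a, b in zip(self.sra_label, other.sra_label))
            and np.array_equal(self.child_sex, other.child_sex)
        )


def recode_to_minor(dataset: TrioDataset) -> TrioDataset:
    """Re-express genotype counts in terms of the parental minor allele.

    The minor allele at each SNP is the one with pooled parental frequency
    below 0.5; a tie is broken toward the lexicographically smaller allele
    string.  Flipping maps every non-missing count ``g`` to ``2 - g``.
    """
    geno = {
        "c": dataset.geno_child.astype(np.int8).copy(),
        "m": dataset.geno_mother.astype(np.int8).copy(),
        "f": dataset.geno_father.astype(np.int8).copy(),
    }
    new_snps = []
    for j, snp in enumerate(dataset.snps):
        counted = snp.allele_b if snp.minor_allele == "b" else snp.allele_a
        other = snp.allele_a if snp.minor_allele == "b" else snp.allele_b
        par = np.concatenate([geno["m"][:, j], geno["f"][:, j]])
        par = par[par != MISSING]
        freq = par.mean() / 2.0 if par.size else 0.0
        flip = freq > 0.5 or (freq == 0.5 and other < counted)
        if flip:
            for g in geno.values():
                nz = g[:, j] != MISSING
                g[nz, j] = 2 - g[nz, j]
            minor = "a" if snp.minor_allele == "b" else "b"
            freq = 1.0 - freq
        else:
            minor = snp.minor_allele
        new_snps.append(replace(snp, minor_allele=minor, parental_maf=float(freq)))
    return TrioDataset(
        dataset.trio_ids,
        new_snps,
        geno["c"],
        geno["m"],
        geno["f"],
        dataset.exposure,
        dataset.sra_label,
        dataset.child_sex,
        provenance=dataset.provenance,
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_trios(
    genotype_source: str | Path,
    pedigree: str | Path,
    covariates: str | Path,
    exposure_col: str = "exposure",
) -> TrioDataset:
    """Assemble a :class:`TrioDataset` from a VCF, a FAM pedigree and a
    covariate TSV.

    The FAM file links each affected child to its mother and father; trios
    missing any member in the VCF are excluded (logged).  Genotypes are
    recoded to parental-minor-allele counts, and any Mendelian-inconsistent
    trio x SNP cell is set missing for that trio (logged), on the grounds
    that genotyping error is SNP-local.

    The covariate TSV must have columns ``child_id``, an exposure column
    (0/1/NA, name set by ``exposure_col``) and ``sra_label``, keyed by the
    child's VCF sample id.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(genotype_source))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise TrioDataError("duplicated sample ids in VCF")
    sample_idx = {s: i for i, s in enumerate(samples)}

    snps: list[SnpMeta] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.REF or not var.ALT[0]:
            n_skipped += 1
            logger.warning("skipping non-biallelic record at %s:%s", var.CHROM, var.POS)
            continue
        gt = np.asarray(var.genotypes, dtype=int)  # (n_samples, 3): a1, a2, phased
        alt_counts = np.where(
            (gt[:, 0] < 0) | (gt[:, 1] < 0), MISSING, gt[:, 0] + gt[:, 1]
        )
        snps.append(
            SnpMeta(
                snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=str(var.CHROM),
                pos=int(var.POS),
                allele_a=var.REF,
                allele_b=var.ALT[0],
                minor_allele="b",
            )
        )
        rows.append(alt_counts)
    if n_skipped:
        logger.warning("skipped %d non-biallelic VCF records", n_skipped)
    if not snps:
        raise TrioDataError("no usable biallelic SNPs in VCF")
    geno_all = np.stack(rows, axis=1)  # (n_samples, n_snps)

    # pedigree: child rows are those naming both parents
    fam = pd.read_csv(
        pedigree,
        sep=r"\s+",
        header=None,
        names=["fam_id", "id", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    if fam["id"].duplicated().any():
        raise TrioDataError("duplicated sample ids in FAM")
    cov = pd.read_csv(covariates, sep="\t", dtype={"child_id": str, "sra_label": str})
    for col in ("child_id", exposure_col, "sra_label"):
        if col not in cov.columns:
            raise TrioDataError(f"covariate TSV missing column {col!r}")
    if exposure_col != "exposure":
        cov = cov.rename(columns={exposure_col: "exposure"})
    if cov["child_id"].duplicated().any():
        raise TrioDataError("duplicated child ids in covariate TSV")
    bad_e = cov["exposure"].dropna().astype(float)
    if not np.isin(bad_e, [0.0, 1.0]).all():
        raise TrioDataError("exposure values must be 0, 1 or NA")
    cov = cov.set_index("child_id")

    trio_ids: list[str] = []
    idx_c: list[int] = []
    idx_m: list[int] = []
    idx_f: list[int] = []
    sexes: list[int] = []
    n_incomplete = 0
    for row in fam.itertuples(index=False):
        if row.father in ("0", None) or row.mother in ("0", None):
            continue  # founder line
        members = (row.id, row.mother, row.father)
        if not all(m in sample_idx for m in members):
            n_incomplete += 1
            logger.warning("excluding incomplete trio for child %s", row.id)
            continue
        trio_ids.append(row.id)
        idx_c.append(sample_idx[row.id])
        idx_m.append(sample_idx[row.mother])
        idx_f.append(sample_idx[row.father])
        try:
            sexes.append(int(row.sex))
        except (TypeError, ValueError):
            sexes.append(0)
    if n_incomplete:
        logger.warning("excluded %d incomplete trios", n_incomplete)
    if not trio_ids:
        raise TrioDataError("no complete trios found")

    exposure = np.full(len(trio_ids), np.nan)
    sra = np.full(len(trio_ids), None, dtype=object)
    for i, tid in enumerate(trio_ids):
        if tid in cov.index:
            e = cov.at[tid, "exposure"]
            exposure[i] = float(e) if pd.notna(e) else np.nan
            lab = cov.at[tid, "sra_label"]
            sra[i] = None if pd.isna(lab) else str(lab)

    ds = TrioDataset(
        trio_ids,
        snps,
        geno_all[idx_c],
        geno_all[idx_m],
        geno_all[idx_f],
        exposure,
        sra,
        np.asarray(sexes, dtype=np.int8),
        provenance=str(genotype_source),
    )
    ds = recode_to_minor(ds)

    bad = ~mendelian_consistent(ds.geno_mother, ds.geno_father, ds.geno_child)
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("set %d Mendelian-inconsistent trio x SNP cells missing", n_bad)
        ds.geno_child[bad] = MISSING
    ds.n_mendelian_errors = n_bad  # type: ignore[attr-defined]
    return ds


def write_trio_bundle(
    dataset: TrioDataset, out_dir: str | Path, prefix: str = "cohort"
) -> dict[str, Path]:
    """Write the native trio bundle: uncompressed VCF, FAM pedigree and a
    covariate TSV.  Returns the three paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = out_dir / f"{prefix}.vcf"
    fam_path = out_dir / f"{prefix}.fam"
    cov_path = out_dir / f"{prefix}.cov.tsv"

    suffixes = ("c", "m", "f")
    sample_ids = [f"{tid}_{s}" for tid in dataset.trio_ids for s in suffixes]

    def gt_str(g: int, n_minor_is_b: bool) -> str:
        if g == MISSING:
            return "./."
        alt = g if n_minor_is_b else 2 - g  # count of allele_b
        return ("0/0", "0/1", "1/1")[alt]

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=triogxe\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j, snp in enumerate(dataset.snps):
            minor_is_b = snp.minor_allele == "b"
            fields = [snp.chrom, str(snp.pos), snp.snp_id, snp.allele_a, snp.allele_b,
                      ".", "PASS", ".", "GT"]
            for i in range(len(dataset)):
                for g in (
                    dataset.geno_child[i, j],
                    dataset.geno_mother[i, j],
                    dataset.geno_father[i, j],
                ):
                    fields.append(gt_str(int(g), minor_is_b))
            fh.write("\t".join(fields) + "\n")

    with open(fam_path, "w") as fh:
        for i, tid in enumerate(dataset.trio_ids):
            sex = int(dataset.child_sex[i])
            fh.write(f"{tid}\t{tid}_c\t{tid}_f\t{tid}_m\t{sex}\t2\n")
            fh.write(f"{tid}\t{tid}_m\t0\t0\t2\t1\n")
            fh.write(f"{tid}\t{tid}_f\t0\t0\t1\t1\n")

    cov = pd.DataFrame(
        {
            "child_id": [f"{tid}_c" for tid in dataset.trio_ids],
            "exposure": [
                "" if np.isnan(e) else str(int(e)) for e in dataset.exposure
            ],
            "sra_label": ["" if s is None else s for s in dataset.sra_label],
        }
    )
    cov.to_csv(cov_path, sep="\t", index=False)
    return {"vcf": vcf_path, "fam": fam_path, "covariates": cov_path}


# ---------------------------------------------------------------------------
# Cohort summaries (Tables 1-2 style)
# ---------------------------------------------------------------------------


@dataclass
class CohortSummary:
    """Ancestry x sex counts and ancestry x exposure rates, each with a
    Total row and integer-rounded percentages."""

    sex_counts: pd.DataFrame
    exposure_rates: pd.DataFrame


def summarize_cohort(dataset: TrioDataset) -> CohortSummary:
    """Cross-tabulate the cohort by ancestry group.

    Percentages are rounded to the nearest integer.  Trios with missing
    exposure are excluded from rate denominators and reported as a count;
    empty ancestry groups are simply absent.
    """
    if len(dataset) == 0:
        raise TrioDataError("cannot summarize an empty dataset")
    df = pd.DataFrame(
        {
            "ancestry": [s if s is not None else "Unknown" for s in dataset.sra_label],
            "sex": dataset.child_sex,
            "exposure": dataset.exposure,
        }
    )
    groups = list(pd.unique(df["ancestry"]))

    rows = []
    for grp in groups + ["Total"]:
        sub = df if grp == "Total" else df[df["ancestry"] == grp]
        rows.append(
            {
                "ancestry": grp,
                "males": int((sub["sex"] == 1).sum()),
                "females": int((sub["sex"] == 2).sum()),
                "total": len(sub),
                "pct": int(round(100.0 * len(sub) / len(df))),
            }
        )
    sex_counts = pd.DataFrame(rows)

    rows = []
    for grp in groups + ["Total"]:
        sub = df if grp == "Total" else df[df["ancestry"] == grp]
        known = sub["exposure"].dropna()
        rows.append(
            {
                "ancestry": grp,
                "n": len(sub),
                "n_exposure_known": len(known),
                "n_exposed": int(known.sum()),
                "exposure_pct": (
                    int(round(100.0 * known.mean())) if len(known) else np.nan
                ),
                "n_exposure_missing": int(sub["exposure"].isna().sum()),
            }
        )
    exposure_rates = pd.DataFrame(rows)
    return CohortSummary(sex_counts=sex_counts, exposure_rates=exposure_rates)


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a per-SNP results table as TSV in the fixed column order.

    Floats are written with 6 significant digits so a round-trip read
    returns identical values at that precision.
    """
    out = results.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[RESULT_COLUMNS]
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
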