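"""Synthetic case-parent trio cohorts under exposure-related population
structure.

Two latent subpopulations differ both in their haplotype frequencies over a
linked causal/test locus pair and in their maternal exposure rates.  Disease
risk follows the log-linear model

    log P(D=1 | g, e, x) = b0 + g*bG + e*bE + x*bX
                           + g*e*bGE + g*x*bGX + e*x*bEX + g*e*x*bGEX

evaluated at the child's *causal*-locus genotype and the *true* group
indicator x = s.  Affected-child ascertainment is realized by rejection
sampling on D = 1.  Because exposure and transmissions are independent
within a subpopulation, G and E are conditionally independent given parental
genotypes inside each group — the assumption trio inference rests on — while
the mixture induces spurious interaction at the non-causal test locus when
both haplotype frequencies and exposure rates diverge.

A Balding-Nichols marker panel (independent loci, common Fst divergence from
an ancestral frequency) accompanies each cohort for principal-component
computation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .trio_data import SnpMeta, TrioDataset, recode_to_minor, write_trio_bundle

#: haplotype order over (causal allele, test allele)
HAPLOTYPES = ((0, 0), (0, 1), (1, 0), (1, 1))

CAUSAL_SNP = "sim_causal"
TEST_SNP = "sim_test"


class SimulationError(ValueError):
    """Raised on invalid generative parameters or degenerate sampling."""


@dataclass(frozen=True)
class SimTruth:
    """Full generative log relative risks, referring to the TRUE group
    indicator.  b0, beta_e, beta_x and beta_ex cannot be estimated from
    trios and exist only for simulation."""

    beta0: float = -4.0
    beta_g: float = 0.0
    beta_e: float = 0.0
    beta_x: float = 0.0
    beta_ge: float = 0.0
    beta_gx: float = 0.0
    beta_ex: float = 0.0
    beta_gex: float = 0.0

    def risk(self, g, e, x):
        """P(D=1 | g, e, x) on the probability scale."""
        lp = (
            self.beta0
            + g * self.beta_g
            + e * self.beta_e
            + x * self.beta_x
            + g * e * self.beta_ge
            + g * x * self.beta_gx
            + e * x * self.beta_ex
            + g * e * x * self.beta_gex
        )
        return np.exp(lp)

    def validate(self) -> None:
        g, e, x = np.meshgrid([0, 1, 2], [0, 1], [0, 1])
        if np.any(self.risk(g, e, x) > 1.0):
            raise SimulationError(
                "risk model exceeds probability 1 on the covariate grid"
            )


@dataclass(frozen=True)
class StructureConfig:
    """Population-structure and sampling settings for a simulated cohort.

    ``haplotype_freqs`` is one frequency vector per subpopulation over the
    four (causal, test) haplotypes in :data:`HAPLOTYPES` order.  The marker
    panel diverges from a Uniform(ancestral_maf_range) ancestral frequency
    by a Balding-Nichols Beta draw at the stated Fst.
    """

    subpop_props: tuple = (0.5, 0.5)
    exposure_rate: tuple = (0.04, 0.41)
    haplotype_freqs: tuple = (
        (0.45, 0.45, 0.05, 0.05),
        (0.45, 0.15, 0.05, 0.35),
    )
    subpop_names: tuple = ("East Asian", "European")
    n_markers: int = 300
    fst: float = 0.15
    ancestral_maf_range: tuple = (0.1, 0.9)
    n_trios: int = 500
    seed: int = 0

    @property
    def n_subpops(self) -> int:
        return len(self.subpop_props)

    def validate(self) -> None:
        props = np.asarray(self.subpop_props, dtype=float)
        if props.min() < 0 or not np.isclose(props.sum(), 1.0):
            raise SimulationError("subpop proportions must be >= 0 and sum to 1")
        if len(self.exposure_rate) != self.n_subpops or len(
            self.haplotype_freqs
        ) != self.n_subpops:
            raise SimulationError("per-subpop settings must match subpop count")
        for r in self.exposure_rate:
            if not 0.0 <= r <= 1.0:
                raise SimulationError("exposure rates must lie in [0, 1]")
        for hf in self.haplotype_freqs:
            hf = np.asarray(hf, dtype=float)
            if hf.shape != (4,) or hf.min() < 0 or not np.isclose(hf.sum(), 1.0):
                raise SimulationError("each haplotype frequency vector must sum to 1")
        if not 0.0 < self.fst < 1.0:
            raise SimulationError("Fst must lie in (0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo < hi < 1.0):
            raise SimulationError("degenerate ancestral MAF range")
        if self.n_trios < 1:
            raise SimulationError("n_trios must be positive")


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

_HAP_G = np.array([h[0] for h in HAPLOTYPES])  # causal allele per haplotype
_HAP_T = np.array([h[1] for h in HAPLOTYPES])  # test allele per haplotype


def _draw_candidates(structure: StructureConfig, truth: SimTruth, size: int, rng):
    """One vectorized batch of candidate trios; returns dict of arrays plus
    the acceptance mask."""
    s = rng.choice(structure.n_subpops, size=size, p=np.asarray(structure.subpop_props))
    hf = np.asarray(structure.haplotype_freqs, dtype=float)
    cum = hf.cumsum(axis=1)[s]  # (size, 4) per-candidate cumulative freqs
    # four parental haplotypes per candidate: mother x2, father x2
    u = rng.random((size, 4))
    haps = (u[:, :, None] > cum[:, None, :]).sum(axis=2)  # (size, 4) in 0..3
    # transmitted haplotype: uniform pick per parent
    pick_m = rng.integers(0, 2, size=size)
    pick_f = rng.integers(0, 2, size=size)
    tm = haps[np.arange(size), pick_m]
    tf = haps[np.arange(size), 2 + pick_f]
    g_causal = _HAP_G[tm] + _HAP_G[tf]
    e = (rng.random(size) < np.asarray(structure.exposure_rate)[s]).astype(int)
    accept = rng.random(size) < truth.risk(g_causal, e, s.astype(float))
    return {"s": s, "haps": haps, "tm": tm, "tf": tf, "e": e}, accept


def simulate_cohort(
    truth: SimTruth,
    structure: StructureConfig,
    rng: np.random.Generator | None = None,
) -> tuple[TrioDataset, pd.DataFrame]:
    """Generate ``n_trios`` ascertained affected-child trios.

    Returns the analysis-ready :class:`TrioDataset` — genotypes at the
    causal and test loci plus the marker panel, maternal exposure and an
    SRA label equal to the subpopulation name — together with a hidden-truth
    table (true subpopulation, causal genotype, parental and transmitted
    haplotypes) that must never enter analysis inputs.
    """
    truth.validate()
    structure.validate()
    if rng is None:
        rng = np.random.default_rng(structure.seed)

    n = structure.n_trios
    kept: list[dict] = []
    n_drawn = n_accepted = 0
    while n_accepted < n:
        p_est = max(n_accepted / n_drawn, 1e-3) if n_drawn else 1e-2
        batch = int(min(max((n - n_accepted) / p_est * 1.2, 2000), 2_000_000))
        cand, accept = _draw_candidates(structure, truth, batch, rng)
        n_drawn += batch
        idx = np.flatnonzero(accept)
        n_accepted += idx.size
        kept.append({k: v[idx] for k, v in cand.items()})
        if n_drawn >= 2_000_000 and n_accepted / n_drawn < 1e-6:
            raise SimulationError(
                "acceptance probability below 1e-6: disease too rare under "
                "this risk model"
            )
    acc = {k: np.concatenate([b[k] for b in kept])[:n] for k in kept[0]}

    s, haps, tm, tf, e = acc["s"], acc["haps"], acc["tm"], acc["tf"], acc["e"]
    gc_causal = _HAP_G[tm] + _HAP_G[tf]
    gc_test = _HAP_T[tm] + _HAP_T[tf]
    gm_causal = _HAP_G[haps[:, 0]] + _HAP_G[haps[:, 1]]
    gm_test = _HAP_T[haps[:, 0]] + _HAP_T[haps[:, 1]]
    gf_causal = _HAP_G[haps[:, 2]] + _HAP_G[haps[:, 3]]
    gf_test = _HAP_T[haps[:, 2]] + _HAP_T[haps[:, 3]]

    mk_c, mk_m, mk_f, mk_snps = simulate_marker_panel(structure, subpop=s, rng=rng)

    snps = [
        SnpMeta(CAUSAL_SNP, "1", 1000, "A", "C", minor_allele="b"),
        SnpMeta(TEST_SNP, "1", 1500, "A", "G", minor_allele="b"),
    ] + mk_snps
    trio_ids = [f"trio{i:05d}" for i in range(n)]
    geno_c = np.column_stack([gc_causal, gc_test, mk_c]).astype(np.int8)
    geno_m = np.column_stack([gm_causal, gm_test, mk_m]).astype(np.int8)
    geno_f = np.column_stack([gf_causal, gf_test, mk_f]).astype(np.int8)
    names = np.asarray(structure.subpop_names, dtype=object)
    sex = rng.integers(1, 3, size=n).astype(np.int8)

    ds = TrioDataset(
        trio_ids,
        snps,
        geno_c,
        geno_m,
        geno_f,
        exposure=e.astype(float),
        sra_label=names[s],
        child_sex=sex,
        provenance="triogxe.synthetic_cohort",
    )
    ds = recode_to_minor(ds)

    hidden = pd.DataFrame(
        {
            "trio_id": trio_ids,
            "subpop": s,
            "g_causal_child": gc_causal,
            "hap_m1": haps[:, 0],
            "hap_m2": haps[:, 1],
            "hap_f1": haps[:, 2],
            "hap_f2": haps[:, 3],
            "hap_transmitted_m": tm,
            "hap_transmitted_f": tf,
        }
    )
    return ds, hidden


def simulate_marker_panel(
    structure: StructureConfig,
    subpop: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[SnpMeta]]:
    """Independent Balding-Nichols markers for child/mother/father.

    Per-marker subpopulation frequencies are Beta draws around a shared
    ancestral frequency at the configured Fst; parents are HWE within their
    subpopulation and children receive one transmitted allele per parent.
    ``subpop`` aligns the panel with an existing cohort; if omitted, labels
    are drawn from the configured proportions.
    """
    structure.validate()
    if structure.n_markers < 2:
        raise SimulationError("need at least 2 markers")
    if rng is None:
        rng = np.random.default_rng(structure.seed + 1)
    if subpop is None:
        subpop = rng.choice(
            structure.n_subpops,
            size=structure.n_trios,
            p=np.asarray(structure.subpop_props),
        )
    subpop = np.asarray(subpop)
    n, m = subpop.size, structure.n_markers

    lo, hi = structure.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    f = structure.fst
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    # (n_subpops, m) subpopulation allele frequencies
    p_sub = rng.beta(a[None, :], b[None, :], size=(structure.n_subpops, m))
    p_trio = p_sub[subpop]  # (n, m)

    gm = rng.binomial(2, p_trio)
    gf = rng.binomial(2, p_trio)
    gc = rng.binomial(1, gm / 2.0) + rng.binomial(1, gf / 2.0)

    snps = [
        SnpMeta(f"m{j + 1:04d}", "2", 100_000 * (j + 1), "A", "T", minor_allele="b")
        for j in range(m)
    ]
    return gc.astype(np.int8), gm.astype(np.int8), gf.astype(np.int8), snps


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------


def spurious_gxe_scenario(
    n_trios: int = 500, seed: int = 0
) -> tuple[SimTruth, StructureConfig]:
    """Exposure-related population structure with NO true G x E.

    A strong causal effect (relative risk 3 per copy) at a locus whose
    allele frequency and LD with the test locus differ between the two
    subpopulations, combined with the alcohol-like exposure rates 4% vs
    41%.  The unadjusted 1-df interaction test at the test locus is
    anti-conservative under this preset while the adjusted 2-df tests stay
    valid.
    """
    truth = SimTruth(
        beta0=-5.0,
        beta_g=float(np.log(3.0)),
        beta_e=float(np.log(1.5)),
        beta_x=float(np.log(1.2)),
        beta_ge=0.0,
        beta_gx=0.0,
        beta_ex=0.0,
        beta_gex=0.0,
    )
    structure = StructureConfig(n_trios=n_trios, seed=seed)
    return truth, structure


def single_population_scenario(
    beta_g: float = 0.3,
    beta_ge: float = 0.5,
    exposure_rate: float = 0.41,
    maf: float = 0.3,
    beta0: float = -4.0,
    n_trios: int = 1000,
    seed: int = 0,
) -> tuple[SimTruth, StructureConfig]:
    """A structure-free cohort: two formally identical subpopulations, one
    locus (test == causal via perfectly correlated haplotypes).  Used for
    parameter-recovery studies under the unadjusted model."""
    truth = SimTruth(beta0=beta0, beta_g=beta_g, beta_ge=beta_ge)
    hf = (1.0 - maf, 0.0, 0.0, maf)
    structure = StructureConfig(
        subpop_props=(0.5, 0.5),
        exposure_rate=(exposure_rate, exposure_rate),
        haplotype_freqs=(hf, hf),
        subpop_names=("popA", "popA2"),
        n_markers=50,
        n_trios=n_trios,
        seed=seed,
    )
    return truth, structure


def scenario_to_yaml(
    truth: SimTruth, structure: StructureConfig, path: str | Path
) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"truth": asdict(truth), "structure": _structure_dict(structure)}, fh
        )


def _structure_dict(structure: StructureConfig) -> dict:
    d = asdict(structure)
    d["haplotype_freqs"] = [list(h) for h in structure.haplotype_freqs]
    for key in ("subpop_props", "exposure_rate", "subpop_names", "ancestral_maf_range"):
        d[key] = list(d[key])
    return d


def load_scenario(path: str | Path) -> tuple[SimTruth, StructureConfig]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    truth = SimTruth(**raw["truth"])
    s = raw["structure"]
    s["haplotype_freqs"] = tuple(tuple(h) for h in s["haplotype_freqs"])
    for key in ("subpop_props", "exposure_rate", "subpop_names", "ancestral_maf_range"):
        s[key] = tuple(s[key])
    return truth, StructureConfig(**s)


def write_cohort_bundle(
    dataset: TrioDataset,
    hidden_truth: pd.DataFrame,
    out_dir: str | Path,
    prefix: str = "cohort",
) -> dict[str, Path]:
    """Write the native trio bundle plus the hidden-truth sidecar TSV.

    The sidecar (true subpopulation, causal genotypes, haplotypes) is kept
    out of the analysis inputs by construction."""
    paths = write_trio_bundle(dataset, out_dir, prefix)
    sidecar = Path(out_dir) / f"{prefix}.truth.tsv"
    hidden_truth.to_csv(sidecar, sep="\t", index=False)
    paths["truth"] = sidecar
    return paths
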