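"""Synthetic twin-family cohort generator.

Generates, with the exact statistical structure the downstream analyses
assume: a SNP panel with block LD and fabricated discovery-GWAS summary
statistics; parental haplotypes and Mendelian transmission to MZ/DZ twins
and singleton children; trivariate ACE phenotypes whose additive factors are
partly tagged by the typed panel; 5-point Likert feeding items calibrated to
target reliabilities; and a reporting parent's BMI tied to the child through
the transmission path.

Family structure of the latent factors
--------------------------------------
Additive factors use a parental-midpoint construction -- each parent draws a
standard-normal value and a child receives (mother + father)/2 plus
independent segregation noise with variance 1/2 -- which makes MZ, DZ and
parent-child additive correlations 1, 0.5 and 0.5 simultaneously.  The typed
component is not drawn but *computed* from simulated genotypes transmitted
under Mendelian inheritance, so the same correlations emerge mechanically.
Shared-environment factors are drawn once per family, non-shared factors once
per individual; cross-trait structure is imposed via Cholesky factors of
r_A, r_C and r_E.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .calibrate import inter_item_correlation, likert_attenuation, CalibrationError
from .lms import LmsReference, lms_inverse, synthetic_lms_reference
from .model import GeneratingModel, InvalidConfigurationError

__all__ = [
    "SnpPanel", "FamilyGenotypes", "CohortTables",
    "simulate_panel_and_sumstats", "simulate_family_genotypes",
    "simulate_phenotypes", "simulate_cohort", "simulate_twin_traits",
    "write_cohort", "read_cohort",
]

_N_CHROM = 22
_BLOCK_SPACING_BP = 500_000
_SNP_SPACING_BP = 1_000
_FAMILY_CHUNK = 512


@dataclass
class SnpPanel:
    """Per-SNP records plus the block map used to generate LD."""

    table: pd.DataFrame  # snp_id, chrom, pos, a1, a2, freq_a1, block_id, true_beta

    def __post_init__(self) -> None:
        t = self.table
        for chrom, grp in t.groupby("chrom"):
            if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
                raise InvalidConfigurationError(
                    f"positions must be strictly increasing on chrom {chrom}")
        f = t["freq_a1"].to_numpy()
        if np.any(f < 0.01) or np.any(f > 0.99):
            raise InvalidConfigurationError("freq_a1 must lie in [0.01, 0.99]")

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def block_ids(self) -> np.ndarray:
        return self.table["block_id"].to_numpy()

    @property
    def causal_index(self) -> np.ndarray:
        return np.flatnonzero(self.table["true_beta"].to_numpy() != 0.0)


@dataclass
class FamilyGenotypes:
    """Child dosages plus per-family true-score bookkeeping.

    ``families`` has one row per family (family_id, zygosity); children are
    stored row-wise in ``child_dosages`` with ``child_family`` giving each
    child's family row index and ``child_twin_order`` in {1, 2}.  True typed
    polygenic scores (standardized against the panel's theoretical moments)
    are carried for children and both parents; raw parental dosages are kept
    only on request (they are large).
    """

    families: pd.DataFrame
    child_dosages: np.ndarray          # (n_children, n_snps) int8
    child_family: np.ndarray           # (n_children,) int
    child_twin_order: np.ndarray       # (n_children,) int
    child_true_score: np.ndarray       # (n_children,)
    mother_true_score: np.ndarray      # (n_families,)
    father_true_score: np.ndarray      # (n_families,)
    mother_dosages: np.ndarray | None = None
    father_dosages: np.ndarray | None = None

    @property
    def n_children(self) -> int:
        return self.child_dosages.shape[0]

    def child_ids(self) -> np.ndarray:
        fam = self.families["family_id"].to_numpy(object)
        return np.array([f"{fam[f]}_{o}" for f, o in
                         zip(self.child_family, self.child_twin_order)], object)


@dataclass
class CohortTables:
    """Everything a cohort run reads from disk, as in-memory tables."""

    phenotypes: pd.DataFrame
    dosages: pd.DataFrame              # index individual_id, columns snp ids
    sumstats: pd.DataFrame
    lms: pd.DataFrame
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# panel + summary statistics
# ---------------------------------------------------------------------------

def simulate_panel_and_sumstats(model: GeneratingModel, rng=None):
    """Fabricate a SNP panel (block LD, causal anchors) and its discovery
    summary statistics (observed beta = true beta + estimation noise)."""
    rng = np.random.default_rng(model.seed if rng is None else rng)
    n, bs = model.n_snps, model.ld_block_size
    n_blocks = int(np.ceil(n / bs))
    block_id = np.arange(n) // bs
    within = np.arange(n) % bs

    chrom = (block_id % _N_CHROM) + 1
    pos = 1 + (block_id // _N_CHROM) * _BLOCK_SPACING_BP + within * _SNP_SPACING_BP

    block_freq = rng.uniform(0.1, 0.9, size=n_blocks)
    freq = block_freq[block_id]

    alleles = np.array(list("ACGT"))
    a1 = alleles[rng.integers(0, 4, size=n)]
    a2 = alleles[(np.searchsorted(alleles, a1) + rng.integers(1, 4, size=n)) % 4]

    true_beta = np.zeros(n)
    anchors = np.flatnonzero(within == 0)
    if model.n_causal > 0:
        if model.n_causal <= anchors.size:
            causal = rng.choice(anchors, size=model.n_causal, replace=False)
        else:
            causal = rng.choice(n, size=model.n_causal, replace=False)
        signs = rng.choice([-1.0, 1.0], size=model.n_causal)
        # unit-variance true score on the allele-count scale
        true_beta[causal] = signs / np.sqrt(
            model.n_causal * 2.0 * freq[causal] * (1.0 - freq[causal]))

    se = 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * model.discovery_n)
    beta_obs = true_beta + rng.standard_normal(n) * se
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta_obs / se,
                     np.where(beta_obs != 0, np.inf, 0.0))
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    table = pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(n)],
        "chrom": chrom, "pos": pos, "a1": a1, "a2": a2,
        "freq_a1": freq, "block_id": block_id, "true_beta": true_beta,
    })
    sumstats = pd.DataFrame({
        "SNP": table["snp_id"], "CHR": chrom, "BP": pos, "A1": a1, "A2": a2,
        "FREQ": freq, "BETA": beta_obs, "SE": se, "P": pvals,
    })
    return SnpPanel(table), sumstats


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _family_frame(model: GeneratingModel) -> pd.DataFrame:
    zygosity = (["MZ"] * model.n_mz_pairs + ["DZ_ss"] * model.n_dz_ss_pairs
                + ["DZ_os"] * model.n_dz_os_pairs + ["UNR"] * model.n_unrelated)
    return pd.DataFrame({
        "family_id": [f"F{i + 1:06d}" for i in range(len(zygosity))],
        "zygosity": zygosity,
    })


def _draw_haplotypes(rng, n_hap, block_freq, block_id, within, phi):
    """Haplotype matrix (n_hap, n_snps) under the copy-with-flip block model."""
    n_blocks = block_freq.size
    f32 = block_freq.astype(np.float32)
    anchors = rng.random((n_hap, n_blocks), dtype=np.float32) < f32
    hap = anchors[:, block_id]
    non_anchor = within != 0
    if non_anchor.any() and phi < 1.0:
        cols = np.flatnonzero(non_anchor)
        fresh = rng.random((n_hap, cols.size), dtype=np.float32) < f32[block_id[cols]]
        keep = rng.random((n_hap, cols.size), dtype=np.float32) < np.float32(phi)
        hap[:, cols] = np.where(keep, hap[:, cols], fresh)
    return hap


def _transmit(rng, hap1, hap2, block_id, n_blocks):
    """One transmitted haplotype: whole-block choice between the parent's two."""
    choice = rng.random((hap1.shape[0], n_blocks), dtype=np.float32) < np.float32(0.5)
    pick = choice[:, block_id]
    return np.where(pick, hap1, hap2)


def simulate_family_genotypes(panel: SnpPanel, model: GeneratingModel,
                              rng=None, keep_parent_dosages: bool = False
                              ) -> FamilyGenotypes:
    """Parental haplotypes from allele frequencies; children by Mendelian
    transmission (whole haplotypes per LD block).  MZ twins are a duplicated
    child; DZ twins are independent transmissions from the same parents."""
    if panel.n_snps == 0:
        raise InvalidConfigurationError("empty SNP panel")
    rng = np.random.default_rng(model.seed + 1 if rng is None else rng)
    families = _family_frame(model)
    zyg = families["zygosity"].to_numpy(object)
    n_fam = len(families)
    n_snps = panel.n_snps
    block_id = panel.block_ids
    _, first_idx = np.unique(block_id, return_index=True)
    within = np.arange(n_snps) - first_idx[block_id]
    n_blocks = int(block_id.max()) + 1
    block_freq = np.empty(n_blocks)
    block_freq[block_id] = panel.table["freq_a1"].to_numpy()
    phi = float(np.sqrt(model.within_block_r2))

    beta = panel.table["true_beta"].to_numpy()
    score_mean = float(np.sum(beta * 2.0 * panel.table["freq_a1"].to_numpy()))
    score_var = float(np.sum(beta ** 2 * 2.0 * panel.table["freq_a1"].to_numpy()
                             * (1.0 - panel.table["freq_a1"].to_numpy())))
    score_sd = np.sqrt(score_var) if score_var > 0 else 1.0

    n_child_per_fam = np.where(zyg == "UNR", 1, 2)
    child_family = np.repeat(np.arange(n_fam), n_child_per_fam)
    n_children = child_family.size
    child_twin_order = np.ones(n_children, int)
    # second child of each multi-child family gets order 2
    first_pos = np.searchsorted(child_family, np.arange(n_fam))
    child_twin_order[first_pos[n_child_per_fam == 2] + 1] = 2

    child_dos = np.empty((n_children, n_snps), np.int8)
    mother_score = np.empty(n_fam)
    father_score = np.empty(n_fam)
    child_score = np.empty(n_children)
    mother_dos = np.empty((n_fam, n_snps), np.int8) if keep_parent_dosages else None
    father_dos = np.empty((n_fam, n_snps), np.int8) if keep_parent_dosages else None

    causal_cols = np.flatnonzero(beta != 0.0)
    causal_beta = beta[causal_cols]

    def raw_score(dos):
        if causal_cols.size == 0:
            return np.zeros(dos.shape[0])
        part = dos[:, causal_cols].astype(np.float64) @ causal_beta
        return (part - score_mean) / score_sd

    for lo in range(0, n_fam, _FAMILY_CHUNK):
        hi = min(lo + _FAMILY_CHUNK, n_fam)
        k = hi - lo
        m1 = _draw_haplotypes(rng, k, block_freq, block_id, within, phi)
        m2 = _draw_haplotypes(rng, k, block_freq, block_id, within, phi)
        f1 = _draw_haplotypes(rng, k, block_freq, block_id, within, phi)
        f2 = _draw_haplotypes(rng, k, block_freq, block_id, within, phi)
        mdos = m1.astype(np.int8) + m2.astype(np.int8)
        fdos = f1.astype(np.int8) + f2.astype(np.int8)
        mother_score[lo:hi] = raw_score(mdos)
        father_score[lo:hi] = raw_score(fdos)
        if keep_parent_dosages:
            mother_dos[lo:hi] = mdos
            father_dos[lo:hi] = fdos

        ca = _transmit(rng, m1, m2, block_id, n_blocks).astype(np.int8) \
            + _transmit(rng, f1, f2, block_id, n_blocks).astype(np.int8)
        z_chunk = zyg[lo:hi]
        dz = np.flatnonzero((z_chunk != "UNR") & (z_chunk != "MZ"))
        cb = None
        if dz.size:  # second transmissions only needed for DZ families
            cb = _transmit(rng, m1[dz], m2[dz], block_id, n_blocks).astype(np.int8) \
                + _transmit(rng, f1[dz], f2[dz], block_id, n_blocks).astype(np.int8)
        dz_rank = {int(f): r for r, f in enumerate(dz)}
        for j in range(k):
            fam = lo + j
            rows = first_pos[fam]
            if z_chunk[j] == "UNR":
                child_dos[rows] = ca[j]
            elif z_chunk[j] == "MZ":
                child_dos[rows] = ca[j]
                child_dos[rows + 1] = ca[j]
            else:
                child_dos[rows] = ca[j]
                child_dos[rows + 1] = cb[dz_rank[j]]

    child_score[:] = raw_score(child_dos)
    return FamilyGenotypes(
        families=families, child_dosages=child_dos, child_family=child_family,
        child_twin_order=child_twin_order, child_true_score=child_score,
        mother_true_score=mother_score, father_true_score=father_score,
        mother_dosages=mother_dos, father_dosages=father_dos,
    )


# ---------------------------------------------------------------------------
# latent factors and phenotypes
# ---------------------------------------------------------------------------

def _chol(m, name):
    try:
        return np.linalg.cholesky(np.asarray(m, float))
    except np.linalg.LinAlgError as err:
        raise InvalidConfigurationError(
            f"correlation matrix {name} is not positive definite") from err


def _midpoint_factor(rng, child_family, mz_mask_child, n_fam):
    """Family-structured standard-normal factor: parent midpoint + segregation.

    Returns (child values, mother values, father values).  MZ co-twins share
    their segregation draw (``mz_mask_child`` marks children whose family is
    MZ); the shared draw is keyed on the family so both rows coincide.
    """
    mother = rng.standard_normal(n_fam)
    father = rng.standard_normal(n_fam)
    seg_family = rng.standard_normal(n_fam)  # used by MZ children (shared)
    seg_child = rng.standard_normal(child_family.size)
    seg = np.where(mz_mask_child, seg_family[child_family], seg_child)
    child = 0.5 * (mother[child_family] + father[child_family]) \
        + np.sqrt(0.5) * seg
    return child, mother, father


def _likert_items(rng, trait, k, alpha, levels):
    """Discretized items whose continuous composite equals ``trait`` exactly.

    Item deviations are drawn zero-sum around the trait with a magnitude
    that, after the analytic discretization attenuation, yields the target
    observed inter-item correlation (hence the target alpha).
    """
    rbar_obs = inter_item_correlation(alpha, k)
    rho_d = likert_attenuation(levels)
    rbar_lat = rbar_obs / rho_d ** 2
    if rbar_lat >= 1.0:
        raise CalibrationError(
            f"alpha={alpha} with {levels}-level items needs latent inter-item "
            f"correlation {rbar_lat:.3f} >= 1")
    d2 = k * (1.0 - rbar_lat) / (rbar_lat * (k - 1) + 1.0)
    eta = rng.standard_normal((trait.size, k))
    dev = eta - eta.mean(axis=1, keepdims=True)
    latent = trait[:, None] + np.sqrt(d2) * dev
    sd = np.sqrt(1.0 + d2 * (1.0 - 1.0 / k))
    cuts = stats.norm.ppf(np.arange(1, levels) / levels)
    return np.digitize(latent / sd, cuts) + 1


def simulate_phenotypes(genotypes: FamilyGenotypes, panel: SnpPanel,
                        model: GeneratingModel, rng=None,
                        ref: LmsReference | None = None) -> CohortTables:
    """Trivariate ACE phenotypes, Likert items, raw anthropometrics.

    The BMI additive factor is gps_tag_lambda * (typed true score) plus
    sqrt(1 - lambda^2) * (untyped midpoint factor); cross-trait additive
    structure follows r_a via a Cholesky whose first variable is the BMI
    factor, so the typed tagging survives the mixing untouched.
    """
    rng = np.random.default_rng(model.seed + 2 if rng is None else rng)
    ref = synthetic_lms_reference() if ref is None else ref

    fam = genotypes.families
    n_fam = len(fam)
    cf = genotypes.child_family
    n_children = genotypes.n_children
    zyg_child = fam["zygosity"].to_numpy(object)[cf]
    mz_child = zyg_child == "MZ"
    lam = model.gps_tag_lambda

    # additive component vector z = (bmi-additive, aux2, aux3)
    u_child, u_mother, u_father = _midpoint_factor(rng, cf, mz_child, n_fam)
    z1 = lam * genotypes.child_true_score + np.sqrt(1.0 - lam ** 2) * u_child
    z2, _, _ = _midpoint_factor(rng, cf, mz_child, n_fam)
    z3, _, _ = _midpoint_factor(rng, cf, mz_child, n_fam)
    L_a = _chol(model.r_a, "r_a")
    additive = np.column_stack([z1, z2, z3]) @ L_a.T

    shared = (rng.standard_normal((n_fam, 3)) @ _chol(model.r_c, "r_c").T)[cf]
    # non-shared factors are individual draws even for MZ twins
    nonshared = rng.standard_normal((n_children, 3)) @ _chol(model.r_e, "r_e").T

    ace = model.ace_matrix
    traits = (np.sqrt(ace[:, 0]) * additive + np.sqrt(ace[:, 1]) * shared
              + np.sqrt(ace[:, 2]) * nonshared)
    bmi_sds, restriction, pressure = traits.T

    # reporting parent: BMI phenotype from that parent's own additive value
    father_reports = rng.random(n_fam) < model.prop_father_reporting
    parent_typed = np.where(father_reports, genotypes.father_true_score,
                            genotypes.mother_true_score)
    parent_untyped = np.where(father_reports, u_father, u_mother)
    parent_additive = lam * parent_typed + np.sqrt(1.0 - lam ** 2) * parent_untyped
    parent_bmi_z = (np.sqrt(model.parent_h2) * parent_additive
                    + np.sqrt(1.0 - model.parent_h2) * rng.standard_normal(n_fam))
    parent_sex = np.where(father_reports, "M", "F")
    parent_log_bmi = np.log(23.0) + 0.15 * parent_bmi_z
    parent_height = np.where(father_reports,
                             177.0 + 6.8 * rng.standard_normal(n_fam),
                             163.0 + 6.3 * rng.standard_normal(n_fam))
    parent_weight = np.exp(parent_log_bmi) * (parent_height / 100.0) ** 2

    # ages shared within family; sexes by zygosity
    age_fam = np.clip(rng.normal(model.mean_age, model.sd_age, n_fam), 7.5, 12.5)
    sex_fam = np.where(rng.random(n_fam) < 0.5, "M", "F")
    sex_child = sex_fam[cf].astype(object)
    os_mask = (zyg_child == "DZ_os") & (genotypes.child_twin_order == 2)
    sex_child[os_mask] = np.where(sex_fam[cf[os_mask]] == "M", "F", "M")
    age_child = age_fam[cf]

    bmi_raw = lms_inverse(bmi_sds, age_child, sex_child, ref, "bmi")
    height_raw = lms_inverse(rng.standard_normal(n_children),
                             age_child, sex_child, ref, "height")
    weight_raw = bmi_raw * (height_raw / 100.0) ** 2

    rest_items = _likert_items(rng, restriction, 6,
                               model.item_loadings["restriction"],
                               model.likert_levels)
    press_items = _likert_items(rng, pressure, 4,
                                model.item_loadings["pressure"],
                                model.likert_levels)

    ids = genotypes.child_ids()
    pheno = pd.DataFrame({
        "family_id": fam["family_id"].to_numpy(object)[cf],
        "individual_id": ids,
        "zygosity": zyg_child,
        "sex": sex_child,
        "twin_order": genotypes.child_twin_order,
        "age_years": age_child,
        "height_cm": height_raw,
        "weight_kg": weight_raw,
        "parent_height_cm": parent_height[cf],
        "parent_weight_kg": parent_weight[cf],
        "parent_sex": parent_sex[cf],
    })
    for j in range(6):
        pheno[f"rest_{j + 1}"] = rest_items[:, j]
    for j in range(4):
        pheno[f"press_{j + 1}"] = press_items[:, j]

    truth = pd.DataFrame({
        "individual_id": ids,
        "bmi_sds": bmi_sds, "restriction": restriction, "pressure": pressure,
        "additive_bmi": additive[:, 0],
        "true_typed_score": genotypes.child_true_score,
        "parent_bmi_z": parent_bmi_z[cf],
    })

    dosages = pd.DataFrame(genotypes.child_dosages, index=pd.Index(ids, name="individual_id"),
                           columns=panel.table["snp_id"].to_numpy())
    return CohortTables(phenotypes=pheno, dosages=dosages,
                        sumstats=pd.DataFrame(), lms=ref.table, truth=truth)


def simulate_cohort(model: GeneratingModel, rng=None,
                    keep_parent_dosages: bool = False):
    """Panel + sumstats + genotypes + phenotypes in one seeded call.

    Returns (CohortTables, SnpPanel, FamilyGenotypes); the cohort's sumstats
    table is filled in from the panel simulation.
    """
    master = np.random.default_rng(model.seed) if rng is None else rng
    s1, s2, s3 = master.spawn(3)
    panel, sumstats = simulate_panel_and_sumstats(model, rng=s1)
    genotypes = simulate_family_genotypes(panel, model, rng=s2,
                                          keep_parent_dosages=keep_parent_dosages)
    tables = simulate_phenotypes(genotypes, panel, model, rng=s3)
    tables.sumstats = sumstats
    return tables, panel, genotypes


def simulate_twin_traits(model: GeneratingModel, rng=None):
    """Trait-level twin simulation (no genotypes): the fast path for
    twin-model recovery studies.

    Returns dict group -> array (n_pairs, 6) with columns ordered
    (twin1 traits..., twin2 traits...) in TRAITS order; DZ_ss and DZ_os are
    pooled into 'DZ'.
    """
    rng = np.random.default_rng(model.seed + 3 if rng is None else rng)
    ace = model.ace_matrix
    L_a, L_c, L_e = (_chol(model.r_a, "r_a"), _chol(model.r_c, "r_c"),
                     _chol(model.r_e, "r_e"))
    out = {}
    for group, n_pairs in (("MZ", model.n_mz_pairs),
                           ("DZ", model.n_dz_ss_pairs + model.n_dz_os_pairs)):
        if n_pairs == 0:
            continue
        mother = rng.standard_normal((n_pairs, 3))
        father = rng.standard_normal((n_pairs, 3))
        if group == "MZ":
            seg = rng.standard_normal((n_pairs, 3))
            seg1 = seg2 = seg
        else:
            seg1 = rng.standard_normal((n_pairs, 3))
            seg2 = rng.standard_normal((n_pairs, 3))
        a1 = (0.5 * (mother + father) + np.sqrt(0.5) * seg1) @ L_a.T
        a2 = (0.5 * (mother + father) + np.sqrt(0.5) * seg2) @ L_a.T
        c = rng.standard_normal((n_pairs, 3)) @ L_c.T
        e1 = rng.standard_normal((n_pairs, 3)) @ L_e.T
        e2 = rng.standard_normal((n_pairs, 3)) @ L_e.T
        t1 = np.sqrt(ace[:, 0]) * a1 + np.sqrt(ace[:, 1]) * c + np.sqrt(ace[:, 2]) * e1
        t2 = np.sqrt(ace[:, 0]) * a2 + np.sqrt(ace[:, 1]) * c + np.sqrt(ace[:, 2]) * e2
        out[group] = np.hstack([t1, t2])
    return out


# ---------------------------------------------------------------------------
# file round-trip
# ---------------------------------------------------------------------------

_FILES = {
    "phenotypes": "phenotypes.csv",
    "dosages": "dosages.tsv",
    "sumstats": "sumstats.tsv",
    "lms": "lms_reference.csv",
    "truth": "truth.csv",
}


def write_cohort(tables: CohortTables, directory) -> dict:
    """Write all cohort tables as plain text; returns the file map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in _FILES.items()}
    tables.phenotypes.to_csv(paths["phenotypes"], index=False)
    tables.dosages.to_csv(paths["dosages"], sep="\t")
    tables.sumstats.to_csv(paths["sumstats"], sep="\t", index=False)
    tables.lms.to_csv(paths["lms"], index=False)
    tables.truth.to_csv(paths["truth"], index=False)
    return paths


def read_cohort(directory) -> CohortTables:
    directory = Path(directory)
    pheno = pd.read_csv(directory / _FILES["phenotypes"])
    dosages = pd.read_csv(directory / _FILES["dosages"], sep="\t",
                          index_col="individual_id")
    sumstats = pd.read_csv(directory / _FILES["sumstats"], sep="\t")
    lms = pd.read_csv(directory / _FILES["lms"])
    truth = pd.read_csv(directory / _FILES["truth"])
    return CohortTables(phenotypes=pheno, dosages=dosages, sumstats=sumstats,
                        lms=lms, truth=truth)
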