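"""The generating model for synthetic twin-family cohorts.

``GeneratingModel`` collects every true parameter of the simulated cohort:
zygosity-group sizes, per-trait ACE variance proportions, the aetiological
correlation matrices r_A / r_C / r_E, the strength with which the typed SNP
panel tags the BMI additive factor, the reporting parent's heritability, and
the discovery-GWAS / LD-panel design. The three traits are, in fixed order,
child BMI-SDS and the two parental feeding practices 'restriction' and
'pressure'.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import yaml

TRAITS = ("bmi_sds", "restriction", "pressure")

__all__ = ["TRAITS", "GeneratingModel", "InvalidConfigurationError"]


class InvalidConfigurationError(ValueError):
    pass


def _as_corr(m, name: str) -> np.ndarray:
    m = np.asarray(m, float)
    if m.shape != (3, 3):
        raise InvalidConfigurationError(f"{name} must be 3x3")
    if not np.allclose(m, m.T, atol=1e-10):
        raise InvalidConfigurationError(f"{name} must be symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise InvalidConfigurationError(f"{name} must have unit diagonal")
    if np.linalg.eigvalsh(m).min() < -1e-10:
        raise InvalidConfigurationError(f"{name} is not positive semi-definite")
    return m


@dataclass
class GeneratingModel:
    """True parameters of the synthetic cohort.

    Defaults are pinned to the study conditions the package is verified
    against (group sizes and fitted variance components of a UK twin cohort
    assessed at age ~10); free parameters that those conditions do not pin
    down are filled in by :func:`gxetwin.calibrate.calibrated_model`.
    """

    n_mz_pairs: int = 1636
    n_dz_ss_pairs: int = 1441
    n_dz_os_pairs: int = 1298
    n_unrelated: int = 4445
    # per-trait (A, C, E) variance proportions, trait order = TRAITS
    ace_props: dict = field(default_factory=lambda: {
        "bmi_sds": (0.78, 0.10, 0.12),
        "restriction": (0.43, 0.43, 0.14),
        "pressure": (0.54, 0.37, 0.09),
    })
    r_a: np.ndarray = field(default_factory=lambda: np.eye(3))
    r_c: np.ndarray = field(default_factory=lambda: np.eye(3))
    r_e: np.ndarray = field(default_factory=lambda: np.eye(3))
    gps_tag_lambda: float = 0.2265
    parent_h2: float = 0.35
    n_snps: int = 20_000
    n_causal: int = 1_000
    ld_block_size: int = 5
    within_block_r2: float = 0.25
    discovery_n: float = 339_224.0
    likert_levels: int = 5
    # per-scale target reliabilities (Cronbach's alpha of the item sets)
    item_loadings: dict = field(default_factory=lambda: {
        "restriction": 0.78,
        "pressure": 0.61,
    })
    mean_age: float = 9.91
    sd_age: float = 0.87
    prop_father_reporting: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for trait in TRAITS:
            if trait not in self.ace_props:
                raise InvalidConfigurationError(f"ace_props missing trait {trait!r}")
            a, c, e = self.ace_props[trait]
            if not np.isclose(a + c + e, 1.0, atol=1e-8):
                raise InvalidConfigurationError(
                    f"ACE proportions for {trait!r} must sum to 1 (got {a + c + e})")
            if min(a, c, e) < 0 or max(a, c, e) > 1:
                raise InvalidConfigurationError(
                    f"ACE proportions for {trait!r} must lie in [0, 1]")
        self.r_a = _as_corr(self.r_a, "r_a")
        self.r_c = _as_corr(self.r_c, "r_c")
        self.r_e = _as_corr(self.r_e, "r_e")
        if not 0.0 <= self.gps_tag_lambda <= 1.0:
            raise InvalidConfigurationError("gps_tag_lambda must lie in [0, 1]")
        if not 0.0 <= self.parent_h2 <= 1.0:
            raise InvalidConfigurationError("parent_h2 must lie in [0, 1]")
        if self.n_causal > self.n_snps:
            raise InvalidConfigurationError("n_causal cannot exceed n_snps")
        if not 0.0 <= self.within_block_r2 < 1.0:
            raise InvalidConfigurationError("within_block_r2 must lie in [0, 1)")

    # --- derived quantities -------------------------------------------------
    @property
    def ace_matrix(self) -> np.ndarray:
        """3x2 rows (A, C, E) per trait in TRAITS order, shape (3 traits, 3)."""
        return np.array([self.ace_props[t] for t in TRAITS], float)

    @property
    def n_families(self) -> int:
        return (self.n_mz_pairs + self.n_dz_ss_pairs + self.n_dz_os_pairs
                + self.n_unrelated)

    @property
    def n_children(self) -> int:
        return 2 * (self.n_mz_pairs + self.n_dz_ss_pairs + self.n_dz_os_pairs) \
            + self.n_unrelated

    def implied_phenotypic_corr(self) -> np.ndarray:
        """Model-implied cross-trait phenotypic correlation matrix.

        r_P[i,j] = sqrt(A_i A_j) r_A[i,j] + sqrt(C_i C_j) r_C[i,j]
                   + sqrt(E_i E_j) r_E[i,j].
        """
        m = self.ace_matrix
        sa, sc, se = np.sqrt(m[:, 0]), np.sqrt(m[:, 1]), np.sqrt(m[:, 2])
        return (np.outer(sa, sa) * self.r_a + np.outer(sc, sc) * self.r_c
                + np.outer(se, se) * self.r_e)

    def replace(self, **kw) -> "GeneratingModel":
        return replace(self, **kw)

    # --- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("r_a", "r_c", "r_e"):
            d[k] = np.asarray(d[k]).tolist()
        d["ace_props"] = {t: list(v) for t, v in d["ace_props"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratingModel":
        d = dict(d)
        for k in ("r_a", "r_c", "r_e"):
            if k in d:
                d[k] = np.asarray(d[k], float)
        if "ace_props" in d:
            d["ace_props"] = {t: tuple(v) for t, v in d["ace_props"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratingModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
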