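"""Synthetic cohort generation.

Generates the inputs the fracture-risk pipeline consumes: LD-blocked
biallelic genotype dosages, a sparse polygenic phenotype (heel speed of
sound, SOS) with a target heritability, binary clinical risk factors at
stated prevalences, FRAX-like baseline 10-year fracture probabilities from
a logistic surrogate, and incident major-osteoporotic / hip fracture
outcomes whose per-SD-of-SOS odds ratios are configurable (defaults 1.42
for MOF and 1.80 for hip, the meta-analytic anchors used by the odds-space
adjustment). Event and censoring ages support survival analyses with age as
the time scale.

All randomness flows from explicit integer seeds; identical seeds give
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

RISK_FACTOR_PREVALENCES = {
    # Bernoulli prevalences emulating a mixed-age European biobank cohort
    "prior_fracture": 0.10,
    "smoking": 0.086,
    "corticosteroids": 0.012,
    "rheumatoid_arthritis": 0.010,
    "parental_fracture": 0.14,
    "at_risk_drinking": 0.03,
    "falls": 0.21,
}

#: pooled incident MOF / hip fracture proportions across the four
#: European-ancestry evaluation cohorts (~3.1% and ~1.3%)
DEFAULT_BASE_RATES = (0.031, 0.013)


@dataclasses.dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with per-variant metadata.

    dosages are additive effect-allele counts in [0, 2]; variant_meta has
    one row per variant with columns id, chrom, pos, effect_allele,
    other_allele, eaf (realized effect-allele frequency, strictly in (0,1)).
    """

    dosages: np.ndarray
    variant_meta: pd.DataFrame
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        n, m = self.dosages.shape
        if len(self.variant_meta) != m:
            raise ValueError("variant_meta length does not match dosage columns")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match dosage rows")
        if self.dosages.size and (
            np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2
        ):
            raise ValueError("dosages must lie in [0, 2]")
        ids = self.variant_meta["id"]
        if ids.duplicated().any():
            raise ValueError("variant ids must be unique")
        eaf = self.variant_meta["eaf"].to_numpy()
        if eaf.size and (np.any(eaf <= 0) or np.any(eaf >= 1)):
            raise ValueError("eaf must be strictly within (0, 1)")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        ids = [self.individual_ids[i] for i in np.asarray(index)]
        return GenotypeMatrix(self.dosages[index], self.variant_meta, ids)


@dataclasses.dataclass
class TrueArchitecture:
    """Ground-truth genetic architecture behind a simulated phenotype."""

    causal_weights: np.ndarray
    h2: float
    prop_causal: float


def simulate_genotypes(
    n: int,
    m: int,
    block_size: int = 10,
    rho: float = 0.0,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypeMatrix:
    """Draw biallelic dosages as sums of two correlated haplotypes.

    Within a block of ``block_size`` adjacent variants, haplotype allele
    indicators follow a latent Gaussian AR(1) with parameter ``rho``
    (adjacent-variant haplotype correlation approximately rho; dosage r2
    decays with distance); blocks are mutually independent, emulating LD
    blocks. Effect-allele frequencies are drawn uniformly in ``maf_range``
    and the realized frequency of each column is recorded in the metadata.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if not (0 <= rho < 1):
        raise ValueError(f"rho must be in [0, 1); got rho={rho}")
    low, high = maf_range
    if not (0 < low <= high < 0.5 or (low == high and 0 < low <= 0.5)):
        if not (0 < low <= high <= 0.5):
            raise ValueError(f"invalid maf_range={maf_range}: need 0 < low <= high <= 0.5")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(low, high, size=m)
    thresh = norm.ppf(maf)

    # latent Gaussians for 2n haplotypes, AR(1) restarted at block borders
    z = rng.standard_normal((2 * n, m))
    if rho > 0:
        for j in range(1, m):
            if j % block_size != 0:
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
    alleles = (z < thresh).astype(np.int8)
    dosages = (alleles[:n] + alleles[n:]).astype(float)

    eaf = dosages.mean(axis=0) / 2.0
    # realized frequency must stay inside (0,1) for downstream use
    eaf = np.clip(eaf, 0.5 / (2 * n), 1 - 0.5 / (2 * n))
    n_blocks = (m + block_size - 1) // block_size
    block_of = np.arange(m) // block_size
    chrom = [str(1 + b % 22) for b in block_of]
    pos = [1000 * (1 + j) for j in range(m)]
    meta = pd.DataFrame(
        {
            "id": [f"rs{j + 1}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ["A"] * m,
            "other_allele": ["G"] * m,
            "eaf": eaf,
        }
    )
    ids = [f"id_{i + 1}" for i in range(n)]
    del z, alleles
    return GenotypeMatrix(dosages, meta, ids)


def simulate_sos(
    G: GenotypeMatrix,
    h2: float,
    prop_causal: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, TrueArchitecture]:
    """Simulate a sparse polygenic SOS phenotype with heritability ``h2``.

    sos = G.w + e, with round(prop_causal * m) nonzero Gaussian weights and
    Gaussian noise scaled so var(G.w)/var(sos) ~= h2. The returned phenotype
    is centered and scaled to unit variance.
    """
    if not (0 < h2 < 1):
        raise ValueError(f"h2 must be in (0, 1); got h2={h2}")
    if not (0 < prop_causal <= 1):
        raise ValueError(f"prop_causal must be in (0, 1]; got {prop_causal}")
    rng = np.random.default_rng(seed)
    m = G.n_variants
    n_causal = max(1, round(prop_causal * m))
    causal_idx = rng.choice(m, size=n_causal, replace=False)
    w = np.zeros(m)
    w[causal_idx] = rng.standard_normal(n_causal)
    g = G.dosages @ w
    var_g = g.var()
    if var_g <= 0:
        raise ValueError("genetic component has zero variance; increase n or maf")
    var_e = var_g * (1 - h2) / h2
    e = rng.standard_normal(G.n_individuals) * np.sqrt(var_e)
    sos = g + e
    scale = sos.std()
    sos = (sos - sos.mean()) / scale
    # report weights on the standardized-sos scale
    arch = TrueArchitecture(causal_weights=w / scale, h2=h2, prop_causal=n_causal / m)
    return sos, arch


def simulate_clinical_factors(
    n: int,
    prevalences: dict[str, float] | None = None,
    age_range: tuple[float, float] = (40.0, 69.0),
    prop_female: float = 0.546,
    seed: int = 0,
) -> pd.DataFrame:
    """Independent Bernoulli risk-factor columns plus age and sex.

    Age is uniform on ``age_range``; sex is coded 1 = female with
    probability ``prop_female``.
    """
    prevalences = dict(RISK_FACTOR_PREVALENCES if prevalences is None else prevalences)
    for name, p in prevalences.items():
        if not (0 <= p <= 1):
            raise ValueError(f"prevalence for {name!r} must be in [0, 1]; got {p}")
    if not (0 <= prop_female <= 1):
        raise ValueError(f"prop_female must be in [0, 1]; got {prop_female}")
    rng = np.random.default_rng(seed)
    out = pd.DataFrame({"individual_id": [f"id_{i + 1}" for i in range(n)]})
    out["age"] = rng.uniform(age_range[0], age_range[1], size=n)
    out["sex"] = (rng.random(n) < prop_female).astype(int)
    for name, p in prevalences.items():
        out[name] = (rng.random(n) < p).astype(int)
    return out


def correlate_risk_factor(
    cohort: pd.DataFrame,
    sos: np.ndarray,
    column: str = "prior_fracture",
    target_corr: float = -0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Redraw a binary risk factor so it correlates with the phenotype.

    Risk factors are genotype-independent by default; this knob induces the
    modest negative correlation observed between a skeletal PRS and prior
    fracture (point-biserial ~ -0.1). The Bernoulli probability is tilted
    on the logit scale with slope target_corr / sqrt(prev*(1-prev)), a
    first-order calibration that lands near the target for small |corr|.
    """
    if column not in cohort.columns:
        raise KeyError(f"unknown risk-factor column {column!r}")
    prev = float(cohort[column].mean())
    if not (0 < prev < 1):
        raise ValueError(f"column {column!r} has degenerate prevalence {prev}")
    z = np.asarray(sos, dtype=float)
    z = (z - z.mean()) / z.std()
    b = target_corr / np.sqrt(prev * (1 - prev))
    p = expit(logit(prev) + b * z)
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    out[column] = (rng.random(len(out)) < p).astype(int)
    return out


def simulate_baseline_risk(
    cohort: pd.DataFrame,
    intercepts: tuple[float, float],
    coefficient_map: dict[str, float],
) -> pd.DataFrame:
    """Fill frax_mof and frax_hip from a logistic surrogate of FRAX.

    logit(frax) = intercept + sum(coef * column). The two intercepts apply
    to MOF and hip respectively; the coefficient map is shared. Outputs are
    strictly inside (0, 1) by construction of the logistic link.
    """
    unknown = [c for c in coefficient_map if c not in cohort.columns]
    if unknown:
        raise KeyError(f"unknown cohort column(s) in coefficient_map: {unknown}")
    lin = np.zeros(len(cohort))
    for col, coef in coefficient_map.items():
        lin = lin + coef * cohort[col].to_numpy(dtype=float)
    out = cohort.copy()
    out["frax_mof"] = expit(intercepts[0] + lin)
    out["frax_hip"] = expit(intercepts[1] + lin)
    return out


DEFAULT_FRAX_COEFFICIENTS = {
    # log-odds per unit; age is centered inside default_baseline_risk
    "age_centered": 0.06,
    "sex": -0.3,
    "prior_fracture": np.log(1.8),
    "smoking": np.log(1.3),
    "corticosteroids": np.log(1.7),
    "rheumatoid_arthritis": np.log(1.4),
    "parental_fracture": np.log(1.5),
}


def default_baseline_risk(
    cohort: pd.DataFrame,
    base_rates: tuple[float, float] = DEFAULT_BASE_RATES,
) -> pd.DataFrame:
    """Convenience wrapper: centered-age logistic FRAX surrogate anchored so
    an average individual sits near the cohort base rates."""
    work = cohort.copy()
    work["age_centered"] = work["age"] - work["age"].mean()
    filled = simulate_baseline_risk(
        work,
        intercepts=(float(logit(base_rates[0])), float(logit(base_rates[1]))),
        coefficient_map=DEFAULT_FRAX_COEFFICIENTS,
    )
    return filled.drop(columns=["age_centered"])


def simulate_fractures(
    cohort: pd.DataFrame,
    sos: np.ndarray,
    per_sd_or_mof: float = 1.42,
    per_sd_or_hip: float = 1.80,
    base_rates: tuple[float, float] = DEFAULT_BASE_RATES,
    followup_years: float = 10.0,
    age_log_or: float = 0.05,
    sex_log_or: float = -0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw incident MOF and hip fracture outcomes plus entry/exit ages.

    Event probabilities follow a logistic model whose log-odds are linear
    in minus the standardized SOS (slope log(per_sd_or)), so a one-SD
    *decrease* in SOS multiplies the odds by the configured ratio, plus
    centered age and sex terms. Cases receive an event age uniform within
    follow-up; non-cases are censored at entry_age + followup_years.
    """
    if per_sd_or_mof <= 0 or per_sd_or_hip <= 0:
        raise ValueError("per-SD odds ratios must be positive")
    sos = np.asarray(sos, dtype=float)
    if len(sos) != len(cohort):
        raise ValueError("sos length does not match cohort")
    sd = sos.std()
    z = (sos - sos.mean()) / sd if sd > 0 else np.zeros_like(sos)
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    age_c = out["age"].to_numpy(dtype=float) - out["age"].mean()
    sex = out["sex"].to_numpy(dtype=float)
    sex_c = sex - sex.mean()
    out["entry_age"] = out["age"].to_numpy(dtype=float)
    exit_age = out["entry_age"].to_numpy() + followup_years
    for outcome, ratio, base in (
        ("incident_mof", per_sd_or_mof, base_rates[0]),
        ("incident_hip", per_sd_or_hip, base_rates[1]),
    ):
        if base == 0:
            events = np.zeros(len(out), dtype=int)
        else:
            lin = (
                logit(base)
                - np.log(ratio) * z
                + age_log_or * age_c
                + sex_log_or * sex_c
            )
            events = (rng.random(len(out)) < expit(lin)).astype(int)
        out[outcome] = events
    # exit age: first-event age for cases (MOF governs the shared clock),
    # administrative censoring otherwise
    any_event = (out["incident_mof"] | out["incident_hip"]).to_numpy(dtype=bool)
    event_age = out["entry_age"].to_numpy() + rng.uniform(
        0.0, followup_years, size=len(out)
    )
    out["exit_age"] = np.where(any_event, event_age, exit_age)
    return out


def split_cohort(
    cohort: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.80, 0.0125, 0.1875),
    forced_test_flag: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign train / select / test labels by a seeded permutation.

    Individuals with a truthy ``forced_test_flag`` column all go to test
    (mirroring holding out everyone with a gold-standard skeletal measure).
    The remainder are permuted; counts use floor for select, then train,
    with the remainder to test.
    """
    fr = np.asarray(fractions, dtype=float)
    if fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError(f"split fractions must be nonnegative and sum to 1; got {tuple(fr)}")
    n = len(cohort)
    split = np.empty(n, dtype=object)
    if forced_test_flag is not None:
        forced = cohort[forced_test_flag].to_numpy(dtype=bool)
    else:
        forced = np.zeros(n, dtype=bool)
    split[forced] = "test"
    free = np.flatnonzero(~forced)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(free)
    n_select = int(np.floor(fr[1] * n))
    n_train = int(np.floor(fr[0] * n))
    n_train = min(n_train, max(0, len(perm) - n_select))
    n_select = min(n_select, len(perm))
    split[perm[:n_select]] = "select"
    split[perm[n_select : n_select + n_train]] = "train"
    split[perm[n_select + n_train :]] = "test"
    out = cohort.copy()
    out["split"] = split
    return out


# ---------------------------------------------------------------------------
# writers


def write_cohort(cohort: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    cohort.to_csv(path, sep=sep, index=False)


def read_cohort(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep)


def write_dosage_matrix(G: GenotypeMatrix, path: str | Path, sep: str = "\t") -> None:
    """Internal delimited matrix: variant metadata columns then one column
    per individual holding the dosage."""
    df = G.variant_meta.copy()
    dos = pd.DataFrame(G.dosages.T, columns=G.individual_ids, index=df.index)
    pd.concat([df, dos], axis=1).to_csv(path, sep=sep, index=False)


def read_dosage_matrix(path: str | Path, sep: str = "\t") -> GenotypeMatrix:
    df = pd.read_csv(path, sep=sep, dtype={"chrom": str})
    meta_cols = ["id", "chrom", "pos", "effect_allele", "other_allele", "eaf"]
    meta = df[meta_cols].copy()
    ind_cols = [c for c in df.columns if c not in meta_cols]
    dosages = df[ind_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(dosages, meta, list(ind_cols))


def write_vcf(G: GenotypeMatrix, path: str | Path, dosage_field: bool = True) -> None:
    """Write genotypes as an uncompressed VCF.

    With ``dosage_field`` the fractional dosage is carried in a DS FORMAT
    field alongside a GT hard call from the rounded dosage; otherwise only
    the GT call is written.
    """
    path = Path(path)
    fmt = "GT:DS" if dosage_field else "GT"
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dosage_field:
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.individual_ids)
            + "\n"
        )
        meta = G.variant_meta
        for j in range(G.n_variants):
            row = meta.iloc[j]
            cells = []
            for d in G.dosages[:, j]:
                gt = gt_codes[int(round(min(max(d, 0.0), 2.0)))]
                cells.append(f"{gt}:{d:g}" if dosage_field else gt)
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['other_allele']}\t"
                f"{row['effect_allele']}\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def write_manifest(path: str | Path, seed: int, parameters: dict) -> None:
    payload = {"seed": seed, "parameters": parameters}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
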