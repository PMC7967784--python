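"""Seeded generator of synthetic death-record cohorts with known structure.

No real death-registry extract ships with this package, so estimation,
inference and evaluation are exercised end-to-end on simulated cohorts
whose generative structure is fully known:

* each region has its own cause-prevalence vector (regional disease mix);
* every internal cause carries a per-(age group, gender) *lethality* —
  the propensity of being the underlying cause when present;
* a record's underlying cause is drawn from its candidates (chain plus
  history) with probability proportional to that stratum lethality, so
  "pick the candidate with the largest conditional death proportion" is
  the Bayes decision rule by construction;
* a configurable fraction of records has an external-cause (ICD-10
  Chapter XX) direct cause, in which case the underlying cause equals
  the direct cause, mirroring the coding rule for external deaths.

:func:`induced_cdcp_oracle` estimates, by brute-force simulation, the
conditional probability the generator induces for each (cause, stratum)
cell — P(cause is underlying | cause appears on the record).  This is
the ground-truth recovery target for the fitted CDCP estimator; it
differs from the raw lethality because it marginalizes over the
co-occurring candidates on each record.

Generation is a pure function of the config (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np

from .estimation import CDCPTable
from .records import AgeGroup, CauseCode, DeathRecord, Gender

__all__ = [
    "GeneratorConfig",
    "default_config",
    "build_code_pools",
    "generate_cohort",
    "induced_cdcp_oracle",
]

#: Age ranges (inclusive) backing the three-level stratification.
_AGE_RANGES = {0: (0, 18), 1: (19, 54), 2: (55, 100)}
_AGE_GROUPS = (AgeGroup.YOUNG, AgeGroup.MIDDLE, AgeGroup.OLD)
_GENDERS = (Gender.MALE, Gender.FEMALE)

#: Fixed pool of syntactically valid external-cause codes (Chapter XX).
EXTERNAL_CODES = ("V03.1", "V43.5", "W13", "W74", "X42", "X70", "Y04", "Y26")

#: Internal-cause chapter letters (A-U; V/W/X/Y are external).
_INTERNAL_LETTERS = "ABCDEGHIJKLMNPQRSTU"

_MAX_CHAIN = 4
_HISTORY_CAP = 8  # generous cap on Poisson history length


def build_code_pools(n_causes: int) -> tuple[list[str], list[str]]:
    """Deterministic pools of syntactically valid ICD-10 codes.

    Internal codes enumerate letter/number combinations over chapters
    A-U; every other code carries a dot sub-code so both 3-character
    category codes and 4-character codes are exercised.
    """
    internal = []
    for i in range(n_causes):
        letter = _INTERNAL_LETTERS[i % len(_INTERNAL_LETTERS)]
        num = (i * 7 + 11) % 100
        code = f"{letter}{num:02d}"
        if i % 2 == 1:
            code += f".{i % 10}"
        internal.append(code)
    if len(set(internal)) != n_causes:  # pragma: no cover - defensive
        raise ValueError("internal code pool collision")
    return internal, list(EXTERNAL_CODES)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    ``cause_prevalence`` has shape (n_regions, n_causes) and rows sum to
    one; ``lethality`` has shape (n_causes, 3, 2) — cause × age group
    (young, middle, old) × gender (male, female) — with values strictly
    inside (0, 1).  ``history_rate`` is the Poisson mean count of
    past-medical-history codes; ``external_fraction`` is the share of
    records whose direct cause is an external-chapter code (and hence
    their own underlying cause).  ``gender_balance`` is P(male).
    """

    n_records: int
    n_causes: int
    n_regions: int
    cause_prevalence: np.ndarray
    lethality: np.ndarray
    chain_length_probs: tuple[float, float, float, float] = (0.10, 0.30, 0.35, 0.25)
    history_rate: float = 0.5
    external_fraction: float = 0.05
    age_group_weights: tuple[float, float, float] = (0.05, 0.25, 0.70)
    gender_balance: float = 0.5
    region_weights: Optional[np.ndarray] = None
    seed: int = 0

    def validate(self) -> None:
        prev = np.asarray(self.cause_prevalence, dtype=float)
        if prev.shape != (self.n_regions, self.n_causes):
            raise ValueError("cause_prevalence must have shape (n_regions, n_causes)")
        if not np.allclose(prev.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("cause_prevalence rows must sum to 1 within 1e-9")
        leth = np.asarray(self.lethality, dtype=float)
        if leth.shape != (self.n_causes, 3, 2):
            raise ValueError("lethality must have shape (n_causes, 3, 2)")
        if not ((leth > 0.0) & (leth < 1.0)).all():
            raise ValueError("lethality values must be strictly inside (0, 1)")
        for vec, name in (
            (self.chain_length_probs, "chain_length_probs"),
            (self.age_group_weights, "age_group_weights"),
        ):
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9")
            if any(p < 0 for p in vec):
                raise ValueError(f"{name} must be non-negative")
        max_len = max(i + 1 for i, p in enumerate(self.chain_length_probs) if p > 0)
        if self.n_causes < max_len:
            raise ValueError(
                f"infeasible config: chains of length {max_len} need at least "
                f"{max_len} distinct causes, have {self.n_causes}"
            )
        if not 0.0 <= self.external_fraction <= 1.0:
            raise ValueError("external_fraction must be in [0, 1]")
        if self.history_rate < 0:
            raise ValueError("history_rate must be ≥ 0")
        if not 0.0 <= self.gender_balance <= 1.0:
            raise ValueError("gender_balance must be in [0, 1]")

    @property
    def internal_codes(self) -> list[str]:
        return build_code_pools(self.n_causes)[0]

    @property
    def external_codes(self) -> list[str]:
        return build_code_pools(self.n_causes)[1]


def default_config(
    n_records: int = 50_000,
    n_causes: int = 40,
    n_regions: int = 5,
    seed: int = 0,
    **overrides,
) -> GeneratorConfig:
    """A cohort configuration emulating a mid-sized city death registry.

    Regional prevalence vectors are drawn from a sparse Dirichlet so a
    handful of causes dominate each region; lethalities are Beta(0.6,
    1.2) clipped to (0.01, 0.99), giving many rarely-underlying causes
    and a few near-certain killers.  Deaths are concentrated in the old
    age group.  All draws use a dedicated child seed so the shape of the
    ground truth is independent of cohort sampling.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2_000_001]))
    prevalence = rng.dirichlet(np.full(n_causes, 0.8), size=n_regions)
    lethality = np.clip(rng.beta(0.6, 1.2, size=(n_causes, 3, 2)), 0.01, 0.99)
    config = GeneratorConfig(
        n_records=n_records,
        n_causes=n_causes,
        n_regions=n_regions,
        cause_prevalence=prevalence,
        lethality=lethality,
        seed=int(seed),
        **overrides,
    )
    config.validate()
    return config


def _sample_arrays(config: GeneratorConfig, rng: np.random.Generator, n: int) -> Dict[str, np.ndarray]:
    """Vectorized sampling core shared by cohort generation and the oracle.

    Returns index arrays; chain/history matrices are padded with -1.
    The underlying column holds an internal-cause index, or -1 for
    external records (whose underlying is their external direct cause).
    """
    n_causes = config.n_causes
    n_ext = len(EXTERNAL_CODES)
    region_w = (
        np.full(config.n_regions, 1.0 / config.n_regions)
        if config.region_weights is None
        else np.asarray(config.region_weights, dtype=float)
    )
    region = rng.choice(config.n_regions, size=n, p=region_w)
    age_group = rng.choice(3, size=n, p=np.asarray(config.age_group_weights))
    lo = np.array([_AGE_RANGES[g][0] for g in range(3)])
    hi = np.array([_AGE_RANGES[g][1] for g in range(3)])
    age = rng.integers(lo[age_group], hi[age_group] + 1)
    gender = (rng.random(n) >= config.gender_balance).astype(np.int64)  # 0=male

    chain_width = min(_MAX_CHAIN, n_causes)
    chain_len = rng.choice(
        np.arange(1, _MAX_CHAIN + 1), size=n, p=np.asarray(config.chain_length_probs)
    )
    hist_cap = max(0, min(_HISTORY_CAP, n_causes - _MAX_CHAIN))
    hist_len = np.minimum(rng.poisson(config.history_rate, size=n), hist_cap)
    hist_len = np.minimum(hist_len, n_causes - chain_len)

    # Weighted sampling without replacement via Gumbel top-k: perturb log
    # prevalence with Gumbel noise and take the top-ranked causes; the
    # first chain_len entries form the chain, the next hist_len the history.
    with np.errstate(divide="ignore"):
        logp = np.log(config.cause_prevalence[region])
    keys = logp + rng.gumbel(size=(n, n_causes))
    take = chain_width + hist_cap
    order = np.argsort(-keys, axis=1)[:, :take]
    n_cand = chain_len + hist_len

    col = np.arange(take)[None, :]
    chain = np.full((n, _MAX_CHAIN), -1, dtype=np.int64)
    chain[:, :chain_width] = np.where(
        col[:, :chain_width] < chain_len[:, None], order[:, :chain_width], -1
    )
    if hist_cap > 0:
        # history slots start right after the chain inside `order`
        shift_idx = np.minimum(chain_len[:, None] + np.arange(hist_cap)[None, :], take - 1)
        hist = np.take_along_axis(order, shift_idx, axis=1)
        hist = np.where(np.arange(hist_cap)[None, :] < hist_len[:, None], hist, -1)
    else:
        hist = np.empty((n, 0), dtype=np.int64)

    is_external = rng.random(n) < config.external_fraction
    ext_code = rng.integers(0, n_ext, size=n)

    # Underlying cause: lethality-proportional draw over the candidates,
    # which form the contiguous prefix order[:, :n_cand].
    valid = col < n_cand[:, None]
    leth = config.lethality[order, age_group[:, None], gender[:, None]]
    weights = np.where(valid, leth, 0.0)
    totals = weights.sum(axis=1, keepdims=True)
    cum = np.cumsum(weights, axis=1)
    u = rng.random(n)[:, None] * totals
    pick = np.minimum((cum < u).sum(axis=1), n_cand - 1)
    underlying = np.take_along_axis(order, pick[:, None], axis=1)[:, 0]
    underlying = np.where(is_external, -1, underlying)

    return {
        "region": region,
        "age": age,
        "age_group": age_group,
        "gender": gender,
        "chain": chain,
        "chain_len": chain_len,
        "history": hist,
        "hist_len": hist_len,
        "is_external": is_external,
        "ext_code": ext_code,
        "underlying": underlying,
    }


def generate_cohort(config: GeneratorConfig, start_id: int = 0) -> list[DeathRecord]:
    """Generate ``config.n_records`` labeled death records.

    Records are a pure function of the config; the same config always
    yields the same cohort.  External records have their direct cause
    replaced by an external-chapter code and labeled as underlying.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    arrays = _sample_arrays(config, rng, config.n_records)
    internal, external = build_code_pools(config.n_causes)
    internal_cc = [CauseCode(c) for c in internal]
    external_cc = [CauseCode(c) for c in external]

    records: list[DeathRecord] = []
    chain_m, hist_m = arrays["chain"], arrays["history"]
    for i in range(config.n_records):
        chain = [internal_cc[j] for j in chain_m[i] if j >= 0]
        if arrays["is_external"][i]:
            chain[0] = external_cc[arrays["ext_code"][i]]
            underlying = chain[0]
        else:
            underlying = internal_cc[arrays["underlying"][i]]
        history = tuple(internal_cc[j] for j in hist_m[i] if j >= 0)
        records.append(
            DeathRecord(
                record_id=f"r{start_id + i:07d}",
                age=int(arrays["age"][i]),
                gender=_GENDERS[arrays["gender"][i]],
                region=f"R{arrays['region'][i]}",
                chain=tuple(chain),
                history=history,
                underlying=underlying,
            )
        )
    return records


def induced_cdcp_oracle(
    config: GeneratorConfig,
    n_monte_carlo: int,
    seed: int,
    chunk_size: int = 200_000,
) -> CDCPTable:
    """Monte-Carlo estimate of the generator's induced conditional
    probability P(cause is underlying | cause appears), per stratum.

    Counts occurrences and underlying deaths directly from the sampling
    core over ``n_monte_carlo`` fresh records (an independent stream
    from ``seed``) and returns the ratio as a raw CDCP table, with
    pooled fallback cells filled from the pooled counts.  Requires at
    least ten times the cohort size so the oracle is tighter than the
    estimate it benchmarks.
    """
    if n_monte_carlo < 10 * config.n_records:
        raise ValueError("n_monte_carlo must be ≥ 10 × config.n_records")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 90_001]))
    n_causes = config.n_causes
    n_ext = len(EXTERNAL_CODES)
    n_all = n_causes + n_ext
    occur = np.zeros((n_all, 3, 2), dtype=np.int64)
    death = np.zeros((n_all, 3, 2), dtype=np.int64)

    done = 0
    while done < n_monte_carlo:
        n = min(chunk_size, n_monte_carlo - done)
        a = _sample_arrays(config, rng, n)
        ag, g = a["age_group"], a["gender"]
        cand = np.concatenate([a["chain"], a["history"]], axis=1)
        # external records: direct cause is replaced by the external code
        cand[a["is_external"], 0] = n_causes + a["ext_code"][a["is_external"]]
        valid = cand >= 0
        rows = np.broadcast_to(ag[:, None], cand.shape)[valid]
        cols = np.broadcast_to(g[:, None], cand.shape)[valid]
        np.add.at(occur, (cand[valid], rows, cols), 1)
        und = np.where(a["is_external"], n_causes + a["ext_code"], a["underlying"])
        np.add.at(death, (und, ag, g), 1)
        done += n

    internal, external = build_code_pools(n_causes)
    codes = internal + external
    table = CDCPTable(transform="raw", smoothing_alpha=0.0)
    g_pool = occur.sum(axis=2), death.sum(axis=2)
    a_pool = occur.sum(axis=1), death.sum(axis=1)
    glob = occur.sum(axis=(1, 2)), death.sum(axis=(1, 2))
    for ci, code in enumerate(codes):
        for gi, ag_enum in enumerate(_AGE_GROUPS):
            for sgi, g_enum in enumerate(_GENDERS):
                if occur[ci, gi, sgi] > 0:
                    table.cells[(code, ag_enum, g_enum)] = (
                        death[ci, gi, sgi] / occur[ci, gi, sgi]
                    )
            if g_pool[0][ci, gi] > 0:
                table.gender_pooled[(code, ag_enum)] = g_pool[1][ci, gi] / g_pool[0][ci, gi]
        for sgi, g_enum in enumerate(_GENDERS):
            if a_pool[0][ci, sgi] > 0:
                table.age_pooled[(code, g_enum)] = a_pool[1][ci, sgi] / a_pool[0][ci, sgi]
        if glob[0][ci] > 0:
            table.global_cells[code] = glob[1][ci] / glob[0][ci]
    return table


def scaled_config(config: GeneratorConfig, n_records: int, seed: Optional[int] = None) -> GeneratorConfig:
    """Same ground truth (prevalence, lethality), different size/seed."""
    return replace(
        config,
        n_records=n_records,
        seed=config.seed if seed is None else int(seed),
    )
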