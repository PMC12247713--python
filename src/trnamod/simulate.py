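"""Synthetic OTTR-seq-style pileups with planted modifications.

Generates multi-species tRNA sets, per-position base-call count tables and
matching ground-truth annotation tables, so every pipeline stage can be
exercised against a known answer without sequencing data.

The noise model mirrors the calling model: each position has a latent MI
frequency drawn from a beta distribution (background means per base, with
G/C running hotter than A/U, or a modification-type-specific mean and
dispersion), read coverage is negative-binomial, non-reference reads are
split multinomially into a deletion fraction and a type-characteristic
mismatch composition.  Cross-species concordance at shared modified sites
is induced by drawing latent logit-MI values from a bivariate normal with a
configurable correlation, which keeps MI in [0, 1] with a single coupling
parameter.

The default scenario plants the headline biology: strong Watson-Crick-face
marks (m1A58, m22G at 10/26, mean MI 0.6-0.8), a rotation-silent
pseudouridine at 55 (mean MI 0.001, expected to stay invisible),
near-detection-floor marks (t6A, Gm, ~1% MI), mutually exclusive
methylation of the acceptor-stem pair 6/67 in the "hyperthermophile" clade,
the G10oU25 determinant of position-10 methylation, and its anti-determinant
relationship with position 26 in one clade but co-occurrence in the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import BASES, Vocabulary, load_vocabulary


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ModificationEffect:
    """Generative parameters of one modification type.

    mean_mi / concentration parameterise the latent beta (alpha = mean*conc,
    beta = (1-mean)*conc); deletion_fraction is the share of non-reference
    reads that are deletions; mismatch_composition weights the non-reference
    bases among the remaining misreads.
    """

    code: str
    affected_base: str
    mean_mi: float
    concentration: float
    deletion_fraction: float
    mismatch_composition: dict = field(default_factory=dict)


def default_effects() -> dict[str, ModificationEffect]:
    """Per-type effect catalog.

    Magnitudes follow the qualitative ordering seen in RT-based profiling:
    Watson-Crick-face methylations (m1A, m22G) misread strongly; m2G is an
    order of magnitude weaker than m22G at the same base; ribose
    methylations and t6A/cnm5U sit at the ~1% detection floor; pseudouridine
    is rotation-silent to the RT.  m22Gm is deletion-enriched.
    """
    E = ModificationEffect
    effects = [
        E("m1A", "A", 0.80, 15, 0.02, {"T": 0.7, "C": 0.2, "G": 0.1}),
        E("m1I", "A", 0.45, 15, 0.02, {"G": 0.7, "C": 0.2, "T": 0.1}),
        E("m1G", "G", 0.55, 15, 0.05, {"T": 0.5, "A": 0.3, "C": 0.2}),
        E("m2G", "G", 0.10, 25, 0.02, {"A": 0.4, "T": 0.4, "C": 0.2}),
        E("m22G", "G", 0.60, 15, 0.08, {"A": 0.4, "T": 0.35, "C": 0.25}),
        E("m22Gm", "G", 0.65, 15, 0.30, {"A": 0.4, "T": 0.35, "C": 0.25}),
        E("Gm", "G", 0.010, 80, 0.05, {}),
        E("t6A", "A", 0.015, 80, 0.10, {"T": 0.5, "G": 0.3, "C": 0.2}),
        E("cnm5U", "T", 0.012, 80, 0.05, {"C": 0.5, "A": 0.3, "G": 0.2}),
        E("Y", "T", 0.001, 300, 0.05, {}),
    ]
    return {e.code: e for e in effects}


@dataclass
class SimulationConfig:
    """The stated world of the default synthetic scenario."""

    seed: int = 0
    species: tuple = ("hyper_A", "hyper_B", "acido_A", "acido_B")
    clade_map: dict = field(default_factory=lambda: {
        "hyper_A": "hyperthermophile", "hyper_B": "hyperthermophile",
        "acido_A": "thermoacidophile", "acido_B": "thermoacidophile"})
    trnas_per_species: int = 40
    coverage_mean: float = 500.0
    coverage_dispersion: float = 10.0
    background_mi: dict = field(default_factory=lambda: {
        "G": 0.015, "C": 0.012, "A": 0.003, "T": 0.003})
    background_concentration: float = 300.0
    effects: dict = field(default_factory=default_effects)
    # planting scheme
    exclusive_6_67: bool = True         # hyperthermophile clade
    c6_fraction: float = 0.10           # precluded (C6) tRNAs, at least 1
    g10u25_fraction: float = 0.6        # among G10 tRNAs
    # cross-species coupling at shared modified sites
    cross_species_correlation: float = 0.9
    pair_logit_mean: float = float(logit(0.35))
    pair_logit_sd: float = 1.25

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), *stream])


_ISOTYPES = [
    ("Ala", "AGC"), ("Arg", "TCT"), ("Asn", "GTT"), ("Asp", "GTC"),
    ("Cys", "GCA"), ("Gln", "TTG"), ("Glu", "TTC"), ("Gly", "GCC"),
    ("His", "GTG"), ("Ile", "GAT"), ("Leu", "TAA"), ("Lys", "TTT"),
    ("Met", "CAT"), ("Phe", "GAA"), ("Pro", "TGG"), ("Ser", "GCT"),
    ("Thr", "TGT"), ("Trp", "CCA"), ("Tyr", "GTA"), ("Val", "TAC"),
    ("iMet", "CAT"),
]

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
# cloverleaf stems on the canonical grid (1-based labels)
_STEMS = ([(i, 73 - i) for i in range(1, 8)]
          + [(i, 35 - i) for i in range(10, 14)]
          + [(i, 70 - i) for i in range(27, 32)]
          + [(i, 114 - i) for i in range(49, 54)])


def _design(config: SimulationConfig, clade: str,
            rng: np.random.Generator) -> list[dict]:
    """Per-tRNA feature plan: controlled bases at analysis positions and
    which modifications to plant.  Deterministic given the rng state."""
    n = config.trnas_per_species
    n_c6 = max(1, round(config.c6_fraction * n))
    n_excl = max(0, ((n - n_c6) * 3 // 5) // 2 * 2)  # even-sized 6/67 group
    hyper = clade == "hyperthermophile"

    plans = []
    for i in range(n):
        iso, anticodon = _ISOTYPES[i % len(_ISOTYPES)]
        plan = {
            "trna": f"{iso}-{anticodon.replace('T', 'U')}-{i // len(_ISOTYPES) + 1}",
            "bases": {}, "mods": [],
        }
        bases, mods = plan["bases"], plan["mods"]
        bases[34], bases[35], bases[36] = anticodon
        bases[54], bases[55], bases[56] = "T", "T", "C"
        bases[74], bases[75], bases[76] = "C", "C", "A"
        mods.append((55, "Y"))  # rotation-silent; planted nearly everywhere

        # acceptor-stem 6/67 design
        if i < n_excl and config.exclusive_6_67 and hyper:
            # eligible at both positions; modified at exactly one
            bases[6], bases[67] = "G", "G"
            mods.append((6, "m22G") if i % 2 == 0 else (67, "m2G"))
        elif i < n_excl + n_c6:
            bases[6], bases[67] = "C", "G"  # C6 precludes m2G/m22G at 6
        else:
            bases[6] = rng.choice(["G", "A", "C"], p=[0.5, 0.25, 0.25])
            bases[67] = _WC[bases[6]]
            if hyper and bases[6] == "G" and rng.random() < 0.7:
                mods.append((6, "m22G"))

        # D-stem 10:25 and 13:22; core 26
        has_g10 = rng.random() < 0.8
        if has_g10:
            bases[10] = "G"
            g10u25 = rng.random() < config.g10u25_fraction
            bases[25] = "T" if g10u25 else "C"
        else:
            bases[10], bases[25] = "A", "T"
            g10u25 = False
        plan["g10u25"] = g10u25
        bases[26] = "G" if rng.random() < 0.85 else "A"

        mod10 = has_g10 and g10u25 and rng.random() < 0.9
        if mod10:
            mods.append((10, "m22G" if hyper or rng.random() < 0.7
                         else "m2G"))
            # weak D-arm motif accompanies modified position 10
            bases[13], bases[22] = ("T", "T") if rng.random() < 0.8 \
                else ("T", "G")
        else:
            bases[13], bases[22] = "C", "G"
        if bases[26] == "G":
            if hyper:
                # anti-determinant clade: G10oU25 excludes the mark at 26
                if not g10u25 and rng.random() < 0.85:
                    mods.append((26, "m22G"))
            else:
                # co-occurrence clade: position 26 modified regardless
                if rng.random() < 0.85:
                    mods.append((26, "m22G" if rng.random() < 0.7
                                 else "m2G"))

        # purine 9 methylation, clade-specific chemistry
        bases[9] = rng.choice(["A", "G"], p=[0.6, 0.4])
        if rng.random() < 0.6:
            if bases[9] == "A":
                mods.append((9, "m1A"))
            elif not hyper:
                mods.append((9, "m1G"))

        # T-arm marks
        bases[58] = "A" if rng.random() < 0.9 else "G"
        if bases[58] == "A" and rng.random() < 0.9:
            mods.append((58, "m1A"))
        bases[57] = "A" if rng.random() < 0.7 else "G"
        if bases[57] == "A" and rng.random() < 0.6:
            mods.append((57, "m1I"))

        # near-floor marks
        bases[37] = "A" if rng.random() < 0.5 else "G"
        if bases[37] == "A" and rng.random() < 0.7:
            mods.append((37, "t6A"))
        if bases[22] == "G" and rng.random() < 0.3:
            mods.append((22, "Gm"))
        plans.append(plan)
    return plans


def _render_sequence(plan: dict, rng: np.random.Generator) -> str:
    seq = list(rng.choice(list("ACGT"), size=76))
    for x, y in _STEMS:
        seq[x - 1] = rng.choice(list("ACGT"))
        seq[y - 1] = _WC[seq[x - 1]]
    for pos, base in plan["bases"].items():
        seq[pos - 1] = base
        # keep unengineered stem partners complementary
        for x, y in _STEMS:
            partner = y if x == pos else x if y == pos else None
            if partner is not None and partner not in plan["bases"]:
                seq[partner - 1] = _WC[base]
    return "".join(seq)


def simulate_trna_set(config: SimulationConfig, species: str,
                      ) -> tuple[dict[str, str], pd.DataFrame]:
    """tRNA sequences and truth annotations for one species.

    Returns (dict trna id -> 76-nt sequence on the standard canonical grid,
    truth annotation table).  Deterministic per (config.seed, species).
    """
    if species not in config.species:
        raise SimulationError(f"unknown species {species!r}")
    clade = config.clade_map[species]
    # species of one clade share a design (orthologous sets), so the rng
    # stream is keyed by clade, not species
    clade_index = sorted(set(config.clade_map.values())).index(clade)
    rng = config.rng(1, clade_index)
    plans = _design(config, clade, rng)
    seqs, truth_rows = {}, []
    for plan in plans:
        seqs[plan["trna"]] = _render_sequence(plan, rng)
        for pos, code in plan["mods"]:
            truth_rows.append({
                "species": species, "trna": plan["trna"],
                "position": str(pos), "code": code, "source": "known"})
    truth = pd.DataFrame(truth_rows,
                         columns=["species", "trna", "position", "code",
                                  "source"])
    return seqs, truth


def _sample_counts(ref: str, coverage: int, mi: float,
                   effect: ModificationEffect | None,
                   rng: np.random.Generator) -> dict[str, int]:
    counts = {b: 0 for b in BASES}
    counts["-"] = 0
    nonref = rng.binomial(coverage, min(max(mi, 0.0), 1.0))
    counts[ref] = coverage - nonref
    if nonref == 0:
        return counts
    del_frac = effect.deletion_fraction if effect else 0.05
    n_del = rng.binomial(nonref, del_frac)
    counts["-"] = n_del
    others = [b for b in BASES if b != ref]
    comp = effect.mismatch_composition if effect else {}
    weights = np.array([comp.get(b, 0.0) for b in others])
    if weights.sum() <= 0:
        weights = np.ones(len(others))
    weights = weights / weights.sum()
    split = rng.multinomial(nonref - n_del, weights)
    for b, k in zip(others, split):
        counts[b] += int(k)
    return counts


def simulate_pileup(config: SimulationConfig, seqs: dict[str, str],
                    truth: pd.DataFrame, species: str,
                    latent_mi: dict | None = None,
                    vocab: Vocabulary | None = None) -> pd.DataFrame:
    """Coverage table for one species given its sequences and truth table.

    Per position: coverage ~ negative binomial; latent MI ~ beta with the
    background or modification-specific mean/dispersion (overridable through
    ``latent_mi``, keyed (trna, position), for cross-species coupling);
    non-reference reads split into deletions and mismatches per the
    modification type.  Raises :class:`SimulationError` when a truth record
    plants a modification on a base the vocabulary disallows.
    """
    vocab = vocab or load_vocabulary()
    sp_index = config.species.index(species) if species in config.species else 0
    rng = config.rng(2, sp_index)
    truth_ix: dict[tuple[str, str], str] = {}
    for _, rec in truth[truth["species"] == species].iterrows():
        truth_ix[(rec["trna"], str(rec["position"]))] = rec["code"]

    disp, mean = config.coverage_dispersion, config.coverage_mean
    p_nb = disp / (disp + mean)
    rows = []
    for trna in sorted(seqs):
        seq = seqs[trna]
        for pos in range(1, len(seq) + 1):
            ref = seq[pos - 1]
            code = truth_ix.get((trna, str(pos)))
            effect = None
            if code is not None:
                effect = config.effects.get(code)
                if effect is None:
                    raise SimulationError(f"no effect parameters for "
                                          f"planted code {code!r}")
                expected = vocab.affected_base.get(code, effect.affected_base)
                if ref != expected:
                    raise SimulationError(
                        f"{species}/{trna}: {code} planted on {ref} at "
                        f"position {pos}, but it modifies {expected}")
                m, conc = effect.mean_mi, effect.concentration
            else:
                m = config.background_mi[ref]
                conc = config.background_concentration
            coverage = int(rng.negative_binomial(disp, p_nb))
            if latent_mi and (trna, str(pos)) in latent_mi:
                mi = float(latent_mi[(trna, str(pos))])
            else:
                mi = float(rng.beta(m * conc, (1 - m) * conc))
            counts = _sample_counts(ref, coverage, mi, effect, rng)
            rows.append({
                "species": species, "trna": trna, "position": str(pos),
                "ref_base": ref, "count_a": counts["A"],
                "count_c": counts["C"], "count_g": counts["G"],
                "count_t": counts["T"], "count_del": counts["-"]})
    return pd.DataFrame(rows)


_MU_CACHE: dict[tuple[float, float], float] = {}


def _logit_mean_for(mean_mi: float, sd: float) -> float:
    """Logit-normal location giving E[logistic(N(mu, sd^2))] = mean_mi.

    Plain logit(mean) undershoots because the logistic is concave above 0.5
    (and convex below); solved by Gauss-Hermite quadrature + root finding.
    """
    from scipy.optimize import brentq

    mean_mi = min(max(mean_mi, 1e-6), 1 - 1e-6)
    key = (round(mean_mi, 9), round(sd, 9))
    if key in _MU_CACHE:
        return _MU_CACHE[key]
    if sd == 0:
        mu = float(logit(mean_mi))
    else:
        nodes, weights = np.polynomial.hermite_e.hermegauss(61)
        def expected(mu):
            return float(weights @ expit(mu + sd * nodes)
                         / weights.sum()) - mean_mi
        mu = float(brentq(expected, -40, 40, xtol=1e-12))
    _MU_CACHE[key] = mu
    return mu


def _clade_latents(config: SimulationConfig, members: list[str],
                   truth: pd.DataFrame, clade_index: int) -> dict[str, dict]:
    """Coupled latent MI values at shared planted sites within one clade.

    Per site, logit-MI values for the clade members are drawn from an
    equicorrelated multivariate normal (correlation
    ``cross_species_correlation``, SD ``pair_logit_sd``) centred on the
    logit of the modification's mean MI, then mapped through the logistic.
    """
    rho, sd = config.cross_species_correlation, config.pair_logit_sd
    k = len(members)
    cov = sd**2 * ((1 - rho) * np.eye(k) + rho * np.ones((k, k)))
    rng = config.rng(4, clade_index)
    latents: dict[str, dict] = {sp: {} for sp in members}
    sites = truth[["trna", "position", "code"]].drop_duplicates()
    for _, rec in sites.iterrows():
        effect = config.effects[rec["code"]]
        mu = _logit_mean_for(effect.mean_mi, sd)
        z = rng.multivariate_normal(np.full(k, mu), cov, method="cholesky")
        for sp, zi in zip(members, z):
            latents[sp][(rec["trna"], str(rec["position"]))] = float(expit(zi))
    return latents


def simulate_scenario(config: SimulationConfig | None = None) -> dict:
    """The default multi-species scenario, end to end.

    Species within a clade share the tRNA design (orthologous sets and a
    common truth table) and their latent MI values at planted sites are
    correlated at ``cross_species_correlation``; background noise is
    independent.  Returns a dict with per-species ``seqs``, a combined
    ``coverage`` table, the ``truth`` annotation table and the
    ``clade_map``.
    """
    config = config or SimulationConfig()
    clades: dict[str, list[str]] = {}
    for sp in config.species:
        clades.setdefault(config.clade_map[sp], []).append(sp)

    seqs_by_species: dict[str, dict[str, str]] = {}
    truths, coverages = [], []
    for clade_index, clade in enumerate(sorted(clades)):
        members = clades[clade]
        latents = None
        for species in members:
            seqs, truth = simulate_trna_set(config, species)
            if latents is None:
                latents = _clade_latents(config, members, truth, clade_index)
            seqs_by_species[species] = seqs
            truths.append(truth)
            coverages.append(simulate_pileup(
                config, seqs, truth, species, latent_mi=latents[species]))
    truth = pd.concat(truths, ignore_index=True)
    coverage = pd.concat(coverages, ignore_index=True)
    return {"config": config, "seqs": seqs_by_species,
            "coverage": coverage, "truth": truth,
            "clade_map": dict(config.clade_map)}


def simulate_species_pair(config: SimulationConfig | None = None,
                          n_sites: int = 60,
                          rho: float | None = None,
                          n_outliers: int = 0,
                          outlier_mi_offset: float = 0.2,
                          noise_sd: float | None = None,
                          species: tuple[str, str] = ("pair_A", "pair_B"),
                          seed_stream: int = 3) -> dict:
    """Two coupled coverage tables sharing modified sites.

    Latent logit-MI values at the shared sites are drawn per site from a
    bivariate normal with correlation ``rho`` (marginal SD ``noise_sd``,
    mean ``pair_logit_mean``), then pushed through the logistic so each
    species' MI stays in [0, 1].  ``n_outliers`` discordant sites are
    planted by offsetting the second species' MI by ``outlier_mi_offset``
    (emulating a diverged modification state).

    Returns a dict with ``coverage_a``/``coverage_b``, shared ``seqs``,
    ``truth`` (for species A; same sites hold in B), ``sites`` (latent and
    per-site metadata incl. ``is_outlier``), and the drawn MI values.
    """
    config = config or SimulationConfig()
    rho = config.cross_species_correlation if rho is None else rho
    if not (0.0 <= rho <= 1.0):
        raise SimulationError(f"correlation must be in [0, 1], got {rho}")
    sd = config.pair_logit_sd if noise_sd is None else noise_sd
    rng = config.rng(seed_stream)

    n_trnas = max(10, int(np.ceil(n_sites / 2)))
    pair_cfg = replace(
        config,
        species=tuple(species),
        clade_map={species[0]: "pair", species[1]: "pair"},
        trnas_per_species=n_trnas,
    )
    seqs, truth = simulate_trna_set(pair_cfg, species[0])
    # shared sites: deterministically pick n_sites planted strong sites
    strong = truth[truth["code"].isin(["m1A", "m22G", "m2G", "m1G", "m1I"])]
    strong = strong.sort_values(["trna", "position"]).reset_index(drop=True)
    if len(strong) < n_sites:
        raise SimulationError(
            f"only {len(strong)} strong planted sites available for a "
            f"{n_sites}-site pair simulation; increase n_sites' tRNA pool")
    sites = strong.iloc[:n_sites].copy()

    mu = config.pair_logit_mean
    cov = np.array([[sd**2, rho * sd**2], [rho * sd**2, sd**2]])
    if sd > 0:
        z = rng.multivariate_normal([mu, mu], cov, size=n_sites,
                                    method="cholesky")
    else:
        z = np.full((n_sites, 2), mu)
    mi_a, mi_b = expit(z[:, 0]), expit(z[:, 1])

    sites["is_outlier"] = False
    if n_outliers:
        # plant at the sites whose MI has the most headroom
        order = np.argsort(np.abs(mi_a - 0.5))
        chosen = order[:n_outliers]
        direction = np.where(mi_a[chosen] <= 0.5, 1.0, -1.0)
        mi_b[chosen] = np.clip(
            mi_a[chosen] + direction * outlier_mi_offset, 0.0, 1.0)
        sites.iloc[chosen, sites.columns.get_loc("is_outlier")] = True
    sites["mi_a"], sites["mi_b"] = mi_a, mi_b

    latent_a = {(r["trna"], r["position"]): r["mi_a"]
                for _, r in sites.iterrows()}
    latent_b = {(r["trna"], r["position"]): r["mi_b"]
                for _, r in sites.iterrows()}
    truth_b = truth.assign(species=species[1])
    coverage_a = simulate_pileup(pair_cfg, seqs, truth, species[0],
                                 latent_mi=latent_a)
    coverage_b = simulate_pileup(pair_cfg, seqs, truth_b, species[1],
                                 latent_mi=latent_b)
    return {"coverage_a": coverage_a, "coverage_b": coverage_b,
            "seqs": seqs, "truth": truth, "truth_b": truth_b,
            "sites": sites.reset_index(drop=True)}
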