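"""Seeded generator of synthetic AFLP/MSAP fingerprint datasets.

The generator emulates a paired multispecies sampling design: a number of
genera, each contributing one restricted-endemic and one widespread
congener, with three populations per species and ~25 individuals per
population.  Band frequencies are population-structured:

* **AFLP** -- each locus gets a genus-level presence probability drawn
  from a Beta prior (congeners are assayed with the same primer panels, so
  the base panel is shared within a genus); each species perturbs the
  locus logits with a Gaussian of sd ``species_sd``, and each population
  adds a further perturbation of sd ``pop_sd``; cells are Bernoulli draws.
* **MSAP** -- each epilocus gets genus-level probabilities of the four
  latent site states (unmethylated, hemi-methylated CHG, methylated CG,
  uninformative/absent site) from a Dirichlet prior; species- and then
  population-level probabilities are resampled as ``Dirichlet(kappa * q)``
  with concentrations ``state_species_concentration`` and
  ``state_pop_concentration``, so the expectation stays exactly the
  genus-level ``q`` at every level; each individual draws a latent state
  and emits the (HpaII, MspI) band pair through the isoschizomer rules --
  unmethylated (1,1), hemi-CHG (1,0), methylated CG (0,1), uninformative
  (0,0).

Sharing the base panels within a genus mirrors the paired congeneric
design: genus-level draws cancel out of every restricted-vs-widespread
contrast, which is precisely why the study pairs species within genera.

``restricted_effect`` (logit-scale dispersion offset, 0 = null model)
multiplies restricted species' locus logits by ``exp(restricted_effect)``
and sharpens their state probabilities by the same power, pushing band
frequencies toward fixation and thereby lowering every diversity index in
the restricted class.  At 0 the two classes are exchangeable.

Scoring noise: every *recorded* profile (original or technical replicate)
carries independent per-cell bit flips at ``scoring_error``, so a replicate
pair mismatches at a locus with probability ``2e(1-e)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .marker_io import (
    BinaryMarkerMatrix,
    Distribution,
    MarkerType,
    MSAPProfileBundle,
    SampleMeta,
)

__all__ = ["SynthConfig", "SpeciesDataset", "simulate_dataset", "expected_state_fractions"]

# latent state order used throughout
STATES = ("unmethylated", "hemi_chg", "meth_cg", "uninformative")
# (hpa, msp) emission per latent state
_EMIT = np.array([[1, 1], [1, 0], [0, 1], [0, 0]], dtype=np.uint8)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the seed fully determines the output."""

    seed: int = 0
    n_genera: int = 7
    populations_per_species: int = 3
    individuals_per_population: int = 25
    n_aflp_loci: int = 300
    n_msap_epiloci: int = 250
    band_freq_prior: tuple[float, float] = (0.2, 1.0)
    species_sd: float = 0.3
    pop_sd: float = 0.5
    state_dirichlet: tuple[float, float, float, float] = (0.35, 0.18, 0.32, 0.25)
    state_species_concentration: float = 40.0
    state_pop_concentration: float = 12.0
    restricted_effect: float = 0.0
    replicate_fraction: float = 0.12
    scoring_error: float = 0.01

    def validate(self) -> None:
        if self.n_genera < 1 or self.populations_per_species < 1:
            raise ValueError("need at least one genus and one population per species")
        if self.individuals_per_population < 2:
            raise ValueError("need >= 2 individuals per population")
        if not 0.0 <= self.replicate_fraction <= 1.0:
            raise ValueError("replicate_fraction must be in [0, 1]")
        if not 0.0 <= self.scoring_error <= 1.0:
            raise ValueError("scoring_error must be in [0, 1]")
        if min(self.band_freq_prior) <= 0 or min(self.state_dirichlet) <= 0:
            raise ValueError("prior shape parameters must be positive")
        if self.state_pop_concentration <= 0:
            raise ValueError("state_pop_concentration must be positive")


@dataclass
class SpeciesDataset:
    """Everything generated for one species."""

    species: str
    aflp: BinaryMarkerMatrix
    msap: MSAPProfileBundle


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return np.log(p / (1 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _flip(bits: np.ndarray, eps: float, rng: np.random.Generator) -> np.ndarray:
    if eps <= 0:
        return bits.copy()
    flips = (rng.random(bits.shape) < eps).astype(np.uint8)
    return bits ^ flips


def _species_samples(
    genus: str, species: str, dist: Distribution, cfg: SynthConfig, rng: np.random.Generator
) -> tuple[list[SampleMeta], list[int]]:
    """Metadata rows (originals then replicates) plus, for each replicate,
    the row index of its original."""
    samples: list[SampleMeta] = []
    for p in range(cfg.populations_per_species):
        pop = f"{species}_p{p + 1}"
        for i in range(cfg.individuals_per_population):
            samples.append(
                SampleMeta(
                    individual_id=f"{species}_p{p + 1}_i{i + 1:02d}",
                    genus=genus,
                    species=species,
                    population=pop,
                    distribution=dist,
                )
            )
    n_orig = len(samples)
    n_rep = int(round(cfg.replicate_fraction * n_orig))
    rep_rows = sorted(rng.choice(n_orig, size=n_rep, replace=False)) if n_rep else []
    for row in rep_rows:
        o = samples[row]
        samples.append(
            SampleMeta(
                individual_id=o.individual_id + "_rep",
                genus=o.genus,
                species=o.species,
                population=o.population,
                distribution=o.distribution,
                replicate_of=o.individual_id,
            )
        )
    return samples, list(rep_rows)


def simulate_dataset(cfg: SynthConfig) -> dict[str, SpeciesDataset]:
    """Generate the full multispecies dataset.

    Returns a mapping ``species name -> SpeciesDataset``; species are named
    ``genus01_restricted`` / ``genus01_widespread`` etc.  Replicate samples
    are appended after the originals of their species.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out: dict[str, SpeciesDataset] = {}
    a, b = cfg.band_freq_prior
    for g in range(cfg.n_genera):
        genus = f"genus{g + 1:02d}"
        # genus-level base panels, shared by the two congeners
        p_genus_logit = _logit(rng.beta(a, b, size=cfg.n_aflp_loci))
        q_genus = rng.dirichlet(np.asarray(cfg.state_dirichlet), size=cfg.n_msap_epiloci)
        for dist in (Distribution.RESTRICTED, Distribution.WIDESPREAD):
            species = f"{genus}_{dist.value}"
            disp = np.exp(cfg.restricted_effect) if dist is Distribution.RESTRICTED else 1.0
            samples, rep_rows = _species_samples(genus, species, dist, cfg, rng)
            n_orig = cfg.populations_per_species * cfg.individuals_per_population

            # ----- AFLP ---------------------------------------------------
            base_logit = (
                p_genus_logit + rng.normal(0.0, cfg.species_sd, cfg.n_aflp_loci)
            ) * disp
            truth = np.empty((n_orig, cfg.n_aflp_loci), dtype=np.uint8)
            for p in range(cfg.populations_per_species):
                pop_logit = base_logit + rng.normal(0.0, cfg.pop_sd, cfg.n_aflp_loci)
                pp = _expit(pop_logit)
                sl = slice(
                    p * cfg.individuals_per_population,
                    (p + 1) * cfg.individuals_per_population,
                )
                truth[sl] = (
                    rng.random((cfg.individuals_per_population, cfg.n_aflp_loci)) < pp
                ).astype(np.uint8)
            recorded = _flip(truth, cfg.scoring_error, rng)
            rep_recorded = _flip(truth[rep_rows], cfg.scoring_error, rng)
            aflp = BinaryMarkerMatrix(
                samples=samples,
                locus_ids=[f"aflp{j + 1:04d}" for j in range(cfg.n_aflp_loci)],
                values=np.vstack([recorded, rep_recorded]),
                marker_type=MarkerType.AFLP,
            )

            # ----- MSAP ---------------------------------------------------
            gsp = rng.standard_gamma(cfg.state_species_concentration * q_genus)
            q_sp = gsp / gsp.sum(axis=1, keepdims=True)
            if disp != 1.0:
                q_sp = q_sp ** disp
                q_sp /= q_sp.sum(axis=1, keepdims=True)
            states = np.empty((n_orig, cfg.n_msap_epiloci), dtype=np.int64)
            kappa = cfg.state_pop_concentration
            for p in range(cfg.populations_per_species):
                # per-epilocus Dirichlet(kappa * q) keeps E[q_pop] = q
                gams = rng.standard_gamma(kappa * q_sp)  # (n_epi, 4)
                q_pop = gams / gams.sum(axis=1, keepdims=True)
                cum = q_pop.cumsum(axis=1)
                sl = slice(
                    p * cfg.individuals_per_population,
                    (p + 1) * cfg.individuals_per_population,
                )
                u = rng.random((cfg.individuals_per_population, cfg.n_msap_epiloci))
                states[sl] = (u[:, :, None] > cum[None, :, :]).sum(axis=2)
            hpa_truth = _EMIT[states, 0]
            msp_truth = _EMIT[states, 1]
            hpa_rec = _flip(hpa_truth, cfg.scoring_error, rng)
            msp_rec = _flip(msp_truth, cfg.scoring_error, rng)
            hpa_rep = _flip(hpa_truth[rep_rows], cfg.scoring_error, rng)
            msp_rep = _flip(msp_truth[rep_rows], cfg.scoring_error, rng)
            epi_ids = [f"epi{j + 1:04d}" for j in range(cfg.n_msap_epiloci)]
            bundle = MSAPProfileBundle(
                hpa=BinaryMarkerMatrix(
                    samples=list(samples),
                    locus_ids=list(epi_ids),
                    values=np.vstack([hpa_rec, hpa_rep]),
                    marker_type=MarkerType.HPA_PROFILE,
                ),
                msp=BinaryMarkerMatrix(
                    samples=list(samples),
                    locus_ids=list(epi_ids),
                    values=np.vstack([msp_rec, msp_rep]),
                    marker_type=MarkerType.MSP_PROFILE,
                ),
            )
            out[species] = SpeciesDataset(species=species, aflp=aflp, msap=bundle)
    return out


def expected_state_fractions(cfg: SynthConfig) -> np.ndarray:
    """Expected fractions of the four recorded (hpa, msp) pair types.

    Order: (1,1), (1,0), (0,1), (0,0).  At ``restricted_effect = 0`` the
    latent-state distribution is the Dirichlet mean in closed form; a
    non-zero dispersion offset sharpens the (random) state probabilities,
    whose expectation has no closed form and is evaluated by a fixed-seed
    Monte-Carlo average.  Scoring noise is then applied analytically as a
    per-bit flip channel.
    """
    cfg.validate()
    alpha = np.asarray(cfg.state_dirichlet, dtype=float)
    if cfg.restricted_effect == 0.0:
        q = alpha / alpha.sum()
    else:
        rng = np.random.default_rng(12345)
        genus = rng.dirichlet(alpha, size=200_000)
        gams = rng.standard_gamma(cfg.state_species_concentration * genus)
        draws = gams / gams.sum(axis=1, keepdims=True)
        widespread = draws.mean(axis=0)
        sharp = draws ** np.exp(cfg.restricted_effect)
        sharp /= sharp.sum(axis=1, keepdims=True)
        q = 0.5 * (widespread + sharp.mean(axis=0))
    eps = cfg.scoring_error
    # channel matrix: true pair -> observed pair under independent bit flips
    chan = np.zeros((4, 4))
    for t in range(4):
        ht, mt = _EMIT[t]
        for o in range(4):
            ho, mo = _EMIT[o]
            ph = eps if ho != ht else 1 - eps
            pm = eps if mo != mt else 1 - eps
            chan[t, o] = ph * pm
    return q @ chan
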