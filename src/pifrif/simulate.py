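"""Two-group bulk RNA-seq simulator with planted structure.

Generates gene x sample negative-binomial count matrices emulating a
6-vs-6 high- versus low-feed-efficiency (HFE/LFE) muscle design, with
three kinds of planted signal that the downstream analyses are built to
detect:

* a minority of strongly differentially expressed genes (1.5-4.5 fold),
* a "mitoproteome" gene set whose DE directions are skewed toward one
  group (default 475:224 up-in-HFE out of 699),
* regulators whose correlation to the DE target set flips sign between
  groups (differential wiring) while the regulator itself is not DE.

Baseline log2 abundances are drawn Normal(4, 2) on an RPM-like scale, so
after reads-per-million scaling the simulated dynamic range resembles a
bulk muscle transcriptome. Counts are negative binomial with a common
overdispersion (default 0.05, i.e. biological CV ~22%, appropriate for
animals of a single genetic line under controlled conditions), scaled to
per-sample library sizes drawn uniformly from a realistic total-read
range.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import CountMatrix, ValidationError

HFE = "HFE"
LFE = "LFE"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults emulate the 6-vs-6 study design."""

    n_genes: int = 12000
    n_per_group: int = 6
    n_regulators: int = 898
    n_rewired: int = 3
    de_fraction: float = 0.05
    fold_change_range: tuple[float, float] = (1.5, 4.5)
    mito_set_size: int = 699
    mito_up_fraction: float = 475 / 699
    mito_fold_change_range: tuple[float, float] = (1.2, 1.8)
    wiring_strength: float = 0.8
    rewiring_mode: str = "sign_flip"  # or "on_off"
    dispersion: float = 0.05
    lfe_dispersion_scale: float = 1.0
    library_size_range: tuple[int, int] = (50_000_000, 85_000_000)
    # Study phenotype: feed efficiency (g gain / g feed) per group.
    fe_mean_hfe: float = 0.65
    fe_mean_lfe: float = 0.46
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if self.n_per_group <= 0:
            raise ValidationError("n_per_group must be positive")
        if self.n_regulators <= 0:
            raise ValidationError("n_regulators must be positive")
        if not 0 <= self.n_rewired <= self.n_regulators:
            raise ValidationError("n_rewired must be in [0, n_regulators]")
        if not 0 <= self.de_fraction < 1:
            raise ValidationError("de_fraction must be in [0, 1)")
        if self.mito_set_size < 0 or self.mito_set_size > self.n_genes:
            raise ValidationError("mito_set_size must be in [0, n_genes]")
        if not 0 < self.mito_up_fraction < 1:
            raise ValidationError("mito_up_fraction must be in (0, 1)")
        if not 0 <= self.wiring_strength <= 1:
            raise ValidationError("wiring_strength must be in [0, 1]")
        if self.rewiring_mode not in ("sign_flip", "on_off"):
            raise ValidationError("rewiring_mode must be sign_flip or on_off")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        if self.lfe_dispersion_scale <= 0:
            raise ValidationError("lfe_dispersion_scale must be positive")
        for name in ("fold_change_range", "mito_fold_change_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must satisfy 0 < low <= high")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValidationError("library_size_range must satisfy 0 < low <= high")
        n_de = self._n_de()
        if self.de_fraction > 0 and n_de < 2:
            raise ValidationError("de_fraction x n_genes must be >= 2")
        if self.mito_set_size + n_de + self.n_regulators > self.n_genes:
            raise ValidationError(
                "n_genes too small for disjoint mito, DE and regulator sets"
            )

    def _n_de(self) -> int:
        return int(round(self.de_fraction * self.n_genes))

    @property
    def fe_contrast_ratio(self) -> float:
        """Planted phenotype contrast: HFE over LFE feed efficiency."""
        return self.fe_mean_hfe / self.fe_mean_lfe

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimulatedDataset:
    """A simulated count matrix plus the planted ground truth."""

    counts: CountMatrix
    truth: pd.DataFrame  # gene, kind ∈ {de, mito}, direction ∈ {+1,-1}, fold
    truth_rewired: set[str]
    regulators: set[str]
    config: SimulationConfig

    def __post_init__(self) -> None:
        genes = set(self.counts.gene_ids)
        if not set(self.truth["gene"]).issubset(genes):
            raise ValidationError("truth gene ids absent from count matrix")
        if not self.regulators.issubset(genes):
            raise ValidationError("regulator ids absent from count matrix")
        if not self.truth_rewired.issubset(self.regulators):
            raise ValidationError("truth_rewired must be a subset of regulators")

    @property
    def truth_de(self) -> dict[str, int]:
        """Planted DE genes (both strong-DE and mito classes) -> direction."""
        return dict(zip(self.truth["gene"], self.truth["direction"]))

    @property
    def truth_strong_de(self) -> dict[str, int]:
        sub = self.truth[self.truth["kind"] == "de"]
        return dict(zip(sub["gene"], sub["direction"]))

    @property
    def truth_mito(self) -> set[str]:
        return set(self.truth.loc[self.truth["kind"] == "mito", "gene"])

    @property
    def groups(self) -> pd.Series:
        return self.counts.groups


def _standardize_within_groups(z: np.ndarray, half: int) -> np.ndarray:
    """Centre and scale a latent sample signal within each group.

    Guarantees the planted regulator signal contributes exactly zero group-mean
    difference on the log scale, so rewired regulators are non-DE by
    construction, not merely in expectation.
    """
    out = z.copy()
    for sl in (slice(0, half), slice(half, None)):
        seg = out[sl]
        sd = seg.std()
        if sd == 0:
            raise ValidationError("degenerate latent signal (need n_per_group >= 2)")
        out[sl] = (seg - seg.mean()) / sd
    return out


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw one dataset under the planted-structure model.

    Deterministic given ``config`` (including ``rng_seed``): identical configs
    produce identical matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    n_g, npg = config.n_genes, config.n_per_group
    n_s = 2 * npg
    gene_ids = np.array([f"G{i:05d}" for i in range(n_g)])
    sample_ids = [f"{HFE}_{i + 1}" for i in range(npg)] + [
        f"{LFE}_{i + 1}" for i in range(npg)
    ]
    groups = pd.Series([HFE] * npg + [LFE] * npg, index=sample_ids, name="group")

    base_log2 = rng.normal(4.0, 2.0, n_g)

    # Disjoint planted sets: mito, strong DE, regulators.
    perm = rng.permutation(n_g)
    n_de = config._n_de()
    mito_idx = perm[: config.mito_set_size]
    de_idx = perm[config.mito_set_size : config.mito_set_size + n_de]
    reg_idx = perm[
        config.mito_set_size + n_de : config.mito_set_size + n_de + config.n_regulators
    ]

    # Per-group log2 means; HFE mean is multiplied by the planted fold.
    delta = np.zeros(n_g)  # log2(HFE/LFE) planted shift
    records: list[tuple[str, str, int, float]] = []

    de_dir = rng.choice([1, -1], size=n_de)
    de_fold = rng.uniform(*config.fold_change_range, size=n_de)
    delta[de_idx] = de_dir * np.log2(de_fold)
    records += [
        (gene_ids[g], "de", int(d), float(f))
        for g, d, f in zip(de_idx, de_dir, de_fold)
    ]

    mito_dir = np.where(
        rng.random(config.mito_set_size) < config.mito_up_fraction, 1, -1
    )
    mito_fold = rng.uniform(*config.mito_fold_change_range, size=config.mito_set_size)
    delta[mito_idx] = mito_dir * np.log2(mito_fold)
    records += [
        (gene_ids[g], "mito", int(d), float(f))
        for g, d, f in zip(mito_idx, mito_dir, mito_fold)
    ]

    # Sample-level log2 mean matrix. The planted fold is split half-and-half
    # across the groups (HFE x sqrt(fold), LFE / sqrt(fold)): the HFE/LFE
    # ratio equals the planted fold while a gene's average abundance stays at
    # its baseline, so DE direction is not confounded with abundance.
    mu = np.tile(base_log2[:, None], (1, n_s)).astype(float)
    mu[:, :npg] += delta[:, None] / 2
    mu[:, npg:] -= delta[:, None] / 2

    # Differential wiring: rewired regulators model one signalling cluster
    # whose influence on its regulon flips between groups. Each DE direction
    # has a single per-sample pathway latent; regulators assigned to that
    # direction track the latent (coefficient 1, plus their own count noise)
    # and the direction's entire strong-DE regulon is driven by the latent
    # with coefficient +c in HFE and -c (sign flip) or 0 (on/off) in LFE.
    # A shared latent avoids superimposing independent signals on common
    # targets, which at small n randomly cancel; direction-coherent regulons
    # keep the signed abundance-x-DE weights of the connectivity score from
    # cancelling. c is calibrated per target so the population regulator-
    # target correlation on the log2 scale equals wiring_strength: count
    # noise with variance (dispersion + 1/mean)/ln(2)^2 would otherwise
    # attenuate the realized correlation below the requested magnitude.
    rewired_idx = reg_idx[: config.n_rewired]
    w = config.wiring_strength
    flip = -1.0 if config.rewiring_mode == "sign_flip" else 0.0
    if config.n_rewired and w > 0:
        ln2sq = np.log(2.0) ** 2
        lib_mid = sum(config.library_size_range) / 2

        def _noise_var(log2_level: np.ndarray) -> np.ndarray:
            mean_count = np.power(2.0, log2_level) * (lib_mid / 1e6)
            return (config.dispersion + 1.0 / np.maximum(mean_count, 1.0)) / ln2sq

        reg_dirs = np.array([1 if k % 2 == 0 else -1 for k in range(config.n_rewired)])
        for direction in (1, -1):
            members = rewired_idx[reg_dirs == direction]
            if len(members) == 0:
                continue
            z = _standardize_within_groups(rng.normal(0.0, 1.0, n_s), npg)
            mu[members, :] += z[None, :]
            block = de_idx[de_dir == direction]
            if len(block) == 0:
                continue
            a_r = 1.0 + float(_noise_var(base_log2[members]).mean())
            rho2a = min(w * w * a_r, 0.97)  # w near 1 is unattainable under noise
            # group-specific calibration: planted folds move a regulon's
            # abundance, hence its count noise, differently in the two groups
            coef_h = np.sqrt(
                rho2a * _noise_var(base_log2[block] + delta[block] / 2) / (1.0 - rho2a)
            )
            coef_l = np.sqrt(
                rho2a * _noise_var(base_log2[block] - delta[block] / 2) / (1.0 - rho2a)
            )
            mu[block, :npg] += coef_h[:, None] * z[None, :npg]
            mu[block, npg:] += flip * coef_l[:, None] * z[None, npg:]

    # Counts: NB with mean = RPM-like level scaled to the sample library size.
    lib = rng.integers(
        config.library_size_range[0], config.library_size_range[1] + 1, size=n_s
    )
    mean_counts = np.power(2.0, mu) * (lib[None, :] / 1e6)
    alpha = np.full(n_s, config.dispersion)
    alpha[npg:] *= config.lfe_dispersion_scale
    size = 1.0 / alpha  # NB "number of failures" parameter; var = m + alpha m^2
    p = size[None, :] / (size[None, :] + mean_counts)
    counts = rng.negative_binomial(np.broadcast_to(size, p.shape), p)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        groups=groups,
    )
    truth = pd.DataFrame(records, columns=["gene", "kind", "direction", "fold"])
    return SimulatedDataset(
        counts=cm,
        truth=truth,
        truth_rewired={gene_ids[r] for r in rewired_idx},
        regulators={gene_ids[r] for r in reg_idx},
        config=config,
    )


def null_config(**overrides) -> SimulationConfig:
    """A configuration with no planted structure (group means equal)."""
    base = dict(
        de_fraction=0.0,
        mito_set_size=0,
        n_rewired=0,
        wiring_strength=0.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def write_dataset(ds: SimulatedDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset as plain-text files; round-trips through pifrif.io.

    Emits counts.tsv, groups.tsv, regulators.txt, mito_set.txt,
    truth_de.tsv (gene/kind/direction/fold) and truth_rewired.txt.
    """
    from . import io as pio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": directory / "counts.tsv",
        "groups": directory / "groups.tsv",
        "regulators": directory / "regulators.txt",
        "mito_set": directory / "mito_set.txt",
        "truth_de": directory / "truth_de.tsv",
        "truth_rewired": directory / "truth_rewired.txt",
    }
    try:
        pio.write_counts(ds.counts, paths["counts"])
        pio.write_groups(ds.counts.groups, paths["groups"])
        pio.write_gene_set(sorted(ds.regulators), paths["regulators"])
        pio.write_gene_set(sorted(ds.truth_mito), paths["mito_set"])
        ds.truth.to_csv(paths["truth_de"], sep="\t", index=False)
        pio.write_gene_set(sorted(ds.truth_rewired), paths["truth_rewired"])
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise OSError(f"failed writing dataset under {directory}: {exc}") from exc
    return paths
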