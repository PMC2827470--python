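"""Synthetic expression studies, pathway annotations, paired signatures and
qPCR panels with known planted truth.

The generator emulates a two-condition splice-switching oligonucleotide
microarray study: ~27,868 probes measured in biological triplicate for a
treated and a control group, with a planted signature of differentially
expressed probes whose direction split, effect sizes and noise level are
configurable. Pathway annotations emulate an overlapping ontology (a gene
may belong to several pathways); selected pathways can be planted as
enriched in signature genes at a chosen multiplier. Paired cross-platform
signatures and Ct-level qPCR panels carry their own planted truth so every
downstream stage has a recoverable ground truth.

Randomness: a single global seed; every generator derives independent
substreams from it via ``numpy.random.SeedSequence(seed).spawn`` in a fixed,
documented order, so identical (config, seed) reproduce outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .annotations import PathwayAnnotation
from .errors import ConfigurationError, DataError
from .io_formats import SignatureTable

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "ExpressionStudy",
    "generate_study",
    "generate_pathways",
    "generate_paired_signatures",
    "generate_qpcr",
    "write_truth_csv",
    "synthetic_reference_tables",
]

# Substream derivation order from SeedSequence(seed).spawn(6):
# 0 baseline+map, 1 effects, 2 noise, 3 pathways, 4 paired signatures, 5 qPCR.
_N_STREAMS = 6
_STREAM_BASELINE, _STREAM_EFFECTS, _STREAM_NOISE = 0, 1, 2
_STREAM_PATHWAYS, _STREAM_PAIRED, _STREAM_QPCR = 3, 4, 5


def _rng(seed: int, stream: int) -> np.random.Generator:
    children = np.random.SeedSequence(seed).spawn(_N_STREAMS)
    return np.random.default_rng(children[stream])


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale parameters of the synthetic generators.

    Defaults are the emulated study's conditions: a 27,868-probe array in
    biological triplicate, a 961-probe signature with a 90.5%/9.5%
    up/down split, 131 overlapping pathways, ~87.9% cross-platform mapping
    coverage and an ~80% same-direction fraction between paired signatures.
    """

    n_probes: int = 27_868
    n_genes: Optional[int] = None  # default: 1% of genes carry 2 probes
    replicates_per_group: int = 3
    signature_size: int = 961
    frac_up: float = 0.905
    effect_log2fc_mean: float = 2.0   # log2 units
    effect_log2fc_sd: float = 0.5     # log2 units
    noise_sd: float = 0.25            # log2 units, per probe x sample
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    n_pathways: int = 131
    pathway_size_range: tuple[int, int] = (10, 60)
    multi_membership_rate: float = 0.3
    planted_enriched_pathways: dict[str, float] = field(default_factory=dict)
    mapping_coverage: float = 0.879
    concordant_fraction: float = 0.8
    seed: int = 0

    def resolved_n_genes(self) -> int:
        if self.n_genes is not None:
            return self.n_genes
        # 1% of genes get a second probe: n_probes = n_genes * 1.01
        return int(round(self.n_probes / 1.01))

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ConfigurationError("n_probes must be >= 1")
        n_genes = self.resolved_n_genes()
        if not 1 <= n_genes <= self.n_probes:
            raise ConfigurationError("need 1 <= n_genes <= n_probes")
        if self.replicates_per_group < 2:
            raise ConfigurationError(
                "replicates_per_group must be >= 2 (variance undefined)"
            )
        if self.signature_size > self.n_probes:
            raise ConfigurationError("signature_size exceeds n_probes")
        for name in ("frac_up", "multi_membership_rate", "mapping_coverage",
                     "concordant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.pathway_size_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("pathway_size_range must satisfy 1 <= min <= max")
        if self.noise_sd < 0 or self.effect_log2fc_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: expected a mapping of config keys")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        if "pathway_size_range" in raw:
            raw["pathway_size_range"] = tuple(raw["pathway_size_range"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth recorded alongside each synthetic artifact."""

    signature_probes: frozenset[str] = frozenset()
    true_log2fc: dict[str, float] = field(default_factory=dict)
    enriched_pathways: frozenset[str] = frozenset()
    concordance_labels: dict[str, str] = field(default_factory=dict)


@dataclass
class ExpressionStudy:
    """Replicate intensity matrix plus group labels and probe->gene map."""

    intensities: pd.DataFrame          # probes x samples, linear scale, > 0
    group_labels: pd.Series            # sample -> {treated, control}
    probe_gene_map: dict[str, str]
    truth: Optional[PlantedTruth] = None

    def __post_init__(self) -> None:
        if self.intensities.index.duplicated().any():
            raise DataError("duplicate probe ids in intensity matrix")
        missing = set(self.intensities.columns) - set(self.group_labels.index)
        if missing:
            raise DataError(f"samples without group label: {sorted(missing)}")
        groups = set(self.group_labels.loc[list(self.intensities.columns)])
        if groups != {"treated", "control"}:
            raise DataError("both 'treated' and 'control' groups required")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.intensities.columns if self.group_labels[s] == group]

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self.probe_gene_map.values())


# ---------------------------------------------------------------------------
# Expression study generation
# ---------------------------------------------------------------------------

def _probe_ids(n: int) -> list[str]:
    return [f"P{i:06d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(n)]


def generate_study(config: SimulationConfig) -> ExpressionStudy:
    """Generate a two-group replicate study with a planted signature.

    Baseline log2 intensities are log-normal per probe (mean
    ``baseline_log2_mean``, sd ``baseline_log2_sd`` on the log2 scale);
    measurement noise is i.i.d. Gaussian per probe x sample on the log2
    scale. Signature probes are shifted by their true log2 fold change in
    the treated group only, so mean(treated) - mean(control) on the log2
    scale recovers the planted effect exactly when ``noise_sd = 0``.
    """
    config.validate()
    n_probes = config.n_probes
    n_genes = config.resolved_n_genes()
    r = config.replicates_per_group

    rng_base = _rng(config.seed, _STREAM_BASELINE)
    rng_eff = _rng(config.seed, _STREAM_EFFECTS)
    rng_noise = _rng(config.seed, _STREAM_NOISE)

    probes = _probe_ids(n_probes)
    genes = _gene_ids(n_genes)

    # First n_genes probes map 1:1; surplus probes are second (third, ...)
    # probes of randomly chosen genes.
    gene_for_probe = list(genes)
    n_extra = n_probes - n_genes
    if n_extra > 0:
        extra = rng_base.choice(n_genes, size=n_extra, replace=n_extra > n_genes)
        gene_for_probe += [genes[i] for i in extra]
    probe_gene_map = dict(zip(probes, gene_for_probe))

    # Planted signature: which probes, which direction, what effect.
    sig_idx = rng_eff.choice(n_probes, size=config.signature_size, replace=False)
    n_up = int(round(config.frac_up * config.signature_size))
    # Guard: a signature probe must carry a nonzero effect.
    magnitudes = np.maximum(np.abs(
        rng_eff.normal(config.effect_log2fc_mean, config.effect_log2fc_sd,
                       size=config.signature_size)
    ), 1e-6)
    signs = np.ones(config.signature_size)
    signs[n_up:] = -1.0
    order = rng_eff.permutation(config.signature_size)
    effects = (magnitudes * signs)[order]

    true_log2fc = {probes[i]: float(e) for i, e in zip(sig_idx, effects)}

    baseline = rng_base.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                               size=n_probes)
    log2 = np.tile(baseline[:, None], (1, 2 * r))
    if config.noise_sd > 0:
        log2 = log2 + rng_noise.normal(0.0, config.noise_sd, size=log2.shape)
    # Columns 0..r-1 control, r..2r-1 treated.
    shift = np.zeros(n_probes)
    shift[sig_idx] = effects
    log2[:, r:] += shift[:, None]

    samples = [f"ctrl_{i+1}" for i in range(r)] + [f"trt_{i+1}" for i in range(r)]
    intensities = pd.DataFrame(np.exp2(log2), index=pd.Index(probes, name="probe_id"),
                               columns=samples)
    groups = pd.Series(["control"] * r + ["treated"] * r, index=samples, name="group")

    truth = PlantedTruth(
        signature_probes=frozenset(probes[i] for i in sig_idx),
        true_log2fc=true_log2fc,
    )
    return ExpressionStudy(
        intensities=intensities,
        group_labels=groups,
        probe_gene_map=probe_gene_map,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Pathway annotation generation
# ---------------------------------------------------------------------------

def generate_pathways(
    config: SimulationConfig,
    genes: set[str] | frozenset[str],
    signature_genes: set[str] | frozenset[str] | None = None,
) -> tuple[PathwayAnnotation, PlantedTruth]:
    """Generate ``n_pathways`` overlapping gene sets over ``genes``.

    Two-pass construction. Pass 1 draws every pathway disjointly from the
    universe. Pass 2 creates overlap by quota: a fraction of the annotated
    genes (chosen so the final share of multi-member genes equals
    ``multi_membership_rate`` up to rounding) is each inserted into one
    additional pathway, displacing a randomly chosen single-membership
    member, so pathway sizes are preserved and the rate is exact rather
    than sampled (and exactly 0 when the rate is 0).

    Pathways named in ``planted_enriched_pathways`` receive a deterministic
    quota of signature genes: their signature-gene share equals
    ``multiplier`` times the signature's background share, exact up to
    rounding, so the planted enrichment level is a construction, not a
    sample; quota genes are protected from pass-2 replacement. A multiplier
    of 1 leaves the pathway's sampling uniform.
    """
    config.validate()
    if not genes:
        raise ConfigurationError("gene universe is empty")
    lo, hi = config.pathway_size_range
    if hi > len(genes):
        raise ConfigurationError(
            f"pathway_size_range max {hi} exceeds universe size {len(genes)}"
        )
    signature_genes = frozenset(signature_genes or ())
    rng = _rng(config.seed, _STREAM_PATHWAYS)

    universe = np.array(sorted(genes))
    is_sig = np.isin(universe, sorted(signature_genes))
    bg_sig_share = is_sig.mean()

    rate = config.multi_membership_rate
    reuse_share = rate / (1.0 + rate)

    names = [f"PW{i:03d}" for i in range(config.n_pathways)]
    sizes = [int(s) for s in rng.integers(lo, hi + 1, size=config.n_pathways)]

    def _draw(pool: np.ndarray, k: int) -> list[int]:
        if k <= 0 or pool.size == 0:
            return []
        return list(rng.choice(pool, size=min(k, pool.size), replace=False))

    # Pass 1: disjoint memberships; planted pathways take their signature
    # quota first, then uniform fills.
    taken = np.zeros(len(universe), dtype=bool)
    members: dict[str, list[int]] = {}
    protected: dict[str, set[int]] = {}
    for name, size in zip(names, sizes):
        multiplier = config.planted_enriched_pathways.get(name, 1.0)
        idx: list[int] = []
        if multiplier != 1.0 and bg_sig_share > 0:
            quota = int(round(min(multiplier * bg_sig_share, 1.0) * size))
            idx += _draw(np.flatnonzero(is_sig & ~taken), quota)
            taken[idx] = True
        idx += _draw(np.flatnonzero(~taken), size - len(idx))
        taken[idx] = True
        if len(idx) < size:  # universe exhausted: allow overlap as fallback
            extra = np.setdiff1d(np.arange(len(universe)), idx)
            idx += _draw(extra, size - len(idx))
        members[name] = idx
        planted = multiplier != 1.0
        protected[name] = {i for i in idx if planted and is_sig[i]}

    # Pass 2: quota overlap. Each chosen gene is inserted into one extra
    # pathway, displacing a single-membership, unprotected member there, so
    # sizes are preserved and exactly M genes end up with k >= 2.
    if reuse_share > 0:
        home: dict[int, str] = {}
        for name, idx in members.items():
            for i in idx:
                home.setdefault(i, name)
        all_protected = set().union(*protected.values())
        annotated_now = sorted(home)
        n_annotated = len(annotated_now)
        m_target = int(round(rate * n_annotated / (1.0 + rate)))
        candidates = rng.permutation(annotated_now)
        multi = list(candidates[:m_target])
        victim_pool = [i for i in candidates[m_target:] if i not in all_protected]
        rng.shuffle(victim_pool)
        member_sets = {name: set(idx) for name, idx in members.items()}
        for g in multi:
            for j, v in enumerate(victim_pool):
                target = home[v]
                if target != home[g] and g not in member_sets[target]:
                    member_sets[target].discard(v)
                    member_sets[target].add(g)
                    victim_pool.pop(j)
                    break
        members = {name: sorted(s) for name, s in member_sets.items()}

    sets = {name: frozenset(universe[idx]) for name, idx in members.items()}
    ann = PathwayAnnotation(sets=sets)
    truth = PlantedTruth(
        enriched_pathways=frozenset(
            n for n, m in config.planted_enriched_pathways.items() if m != 1.0
        ),
    )
    return ann, truth


# ---------------------------------------------------------------------------
# Paired cross-platform signatures
# ---------------------------------------------------------------------------

def generate_paired_signatures(
    config: SimulationConfig,
) -> tuple[SignatureTable, SignatureTable, PlantedTruth, dict]:
    """Two gene-level signature tables on distinct probe namespaces.

    Platform A carries the primary signature; a ``mapping_coverage``
    fraction of A's genes also exists on platform B. Every mapped signature
    gene is significant on both platforms; concordance labels (same /
    opposite fold-change sign on B) are assigned deterministically by quota
    so the planted same-direction fraction is exact, not sampled.

    Returns (sig_a, sig_b, truth, aux) where ``aux`` holds the probe maps
    and platform B's gene universe for use with signature_compare.
    """
    config.validate()
    if config.mapping_coverage == 0.0:
        raise ConfigurationError(
            "mapping_coverage=0 leaves no overlap between the platforms"
        )
    rng = _rng(config.seed, _STREAM_PAIRED)
    n_genes = config.resolved_n_genes()
    genes = np.array(_gene_ids(n_genes))

    n_sig = min(config.signature_size, n_genes)
    sig_genes = rng.choice(genes, size=n_sig, replace=False)

    n_up = int(round(config.frac_up * n_sig))
    mag_a = np.abs(rng.normal(config.effect_log2fc_mean, config.effect_log2fc_sd,
                              size=n_sig))
    mag_a = np.maximum(mag_a, 1e-6)
    sign_a = np.ones(n_sig)
    sign_a[n_up:] = -1.0
    perm = rng.permutation(n_sig)
    lfc_a = (mag_a * sign_a)[perm]
    p_a = rng.uniform(1e-8, 0.05, size=n_sig)

    # Platform B covers mapping_coverage of A's genes; the covered share is
    # an exact quota both within and outside the signature, so the mapped
    # fraction reported downstream equals the configured coverage up to
    # rounding rather than sampling noise.
    non_sig = np.array(sorted(set(genes) - set(sig_genes)))
    n_map_sig = int(round(config.mapping_coverage * n_sig))
    n_map_rest = int(round(config.mapping_coverage * len(non_sig)))
    mapped_genes = frozenset(rng.choice(sig_genes, size=n_map_sig, replace=False)) \
        | frozenset(rng.choice(non_sig, size=n_map_rest, replace=False))
    n_mapped = len(mapped_genes)

    shared_sig = np.array([g for g in sig_genes if g in mapped_genes])
    n_shared = len(shared_sig)
    n_same = int(round(config.concordant_fraction * n_shared))
    # Deterministic quota assignment: first n_same shared genes 'same'.
    labels = {g: ("same" if i < n_same else "opposite")
              for i, g in enumerate(shared_sig)}

    lfc_by_gene = dict(zip(sig_genes, lfc_a))
    mag_b = np.abs(rng.normal(config.effect_log2fc_mean / 2.0,
                              config.effect_log2fc_sd / 2.0, size=n_shared))
    mag_b = np.maximum(mag_b, 1e-6)
    lfc_b = np.array([
        m if (np.sign(lfc_by_gene[g]) > 0) == (labels[g] == "same") else -m
        for g, m in zip(shared_sig, mag_b)
    ])
    p_b = rng.uniform(1e-8, 0.05, size=n_shared)

    sig_a = SignatureTable(
        frame=pd.DataFrame({
            "probe_id": [f"A:{g}" for g in sig_genes],
            "gene_id": sig_genes,
            "log2fc": lfc_a,
            "p_value": p_a,
        }),
        background_size=n_genes,
    )
    sig_b = SignatureTable(
        frame=pd.DataFrame({
            "probe_id": [f"B:{g}" for g in shared_sig],
            "gene_id": shared_sig,
            "log2fc": lfc_b,
            "p_value": p_b,
        }),
        background_size=n_mapped,
    )
    truth = PlantedTruth(concordance_labels=labels)
    aux = {
        "map_a": {f"A:{g}": g for g in genes},
        "map_b": {f"B:{g}": g for g in mapped_genes},
        "universe_b": mapped_genes,
    }
    return sig_a, sig_b, truth, aux


# ---------------------------------------------------------------------------
# qPCR panels
# ---------------------------------------------------------------------------

def generate_qpcr(
    study: ExpressionStudy,
    genes: list[str],
    ct_noise_sd: float,
    seed: int,
):
    """Ct-level qPCR panel consistent with the study's planted fold changes.

    For each gene, target and reference (internal-control) threshold cycles
    are constructed so that -ddCt equals the gene's planted array log2 fold
    change; Gaussian noise of sd ``ct_noise_sd`` is added to every Ct value
    independently (Ct-level replication). At zero noise the ddCt estimate
    recovers the truth exactly.
    """
    from .qpcr_validate import QpcrMeasurement

    known = study.gene_ids
    for g in genes:
        if g not in known:
            raise DataError(f"unknown gene id {g!r}")
    if ct_noise_sd < 0:
        raise ConfigurationError("ct_noise_sd must be non-negative")
    rng = _rng(seed, _STREAM_QPCR)
    truth = study.truth
    lfc_by_gene: dict[str, float] = {}
    if truth is not None:
        for probe, lfc in truth.true_log2fc.items():
            g = study.probe_gene_map[probe]
            # A gene's planted effect: keep the largest-magnitude probe.
            if g not in lfc_by_gene or abs(lfc) > abs(lfc_by_gene[g]):
                lfc_by_gene[g] = lfc

    r = sum(study.group_labels == "treated")
    panel = []
    for g in genes:
        lfc = lfc_by_gene.get(g, 0.0)
        ref = 15.0
        tgt_ctrl = float(rng.uniform(22.0, 28.0))
        tgt_trt = tgt_ctrl - lfc  # one cycle = one doubling

        def noisy(mean: float, n: int) -> np.ndarray:
            base = np.full(n, mean)
            if ct_noise_sd > 0:
                base = base + rng.normal(0.0, ct_noise_sd, size=n)
            return base

        panel.append(QpcrMeasurement(
            gene_id=g,
            ct_target_treated=noisy(tgt_trt, r),
            ct_reference_treated=noisy(ref, r),
            ct_target_control=noisy(tgt_ctrl, r),
            ct_reference_control=noisy(ref, r),
        ))
    return panel


# ---------------------------------------------------------------------------
# Truth sidecar
# ---------------------------------------------------------------------------

def write_truth_csv(study: ExpressionStudy, path: str | Path) -> None:
    """Sidecar CSV: probe_id, gene_id, true_log2fc, in_signature."""
    truth = study.truth or PlantedTruth()
    rows = []
    for probe in study.intensities.index:
        rows.append((
            probe,
            study.probe_gene_map[probe],
            truth.true_log2fc.get(probe, 0.0),
            int(probe in truth.signature_probes),
        ))
    frame = pd.DataFrame(rows, columns=["probe_id", "gene_id", "true_log2fc",
                                        "in_signature"])
    frame.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Study-scale reference stand-ins
# ---------------------------------------------------------------------------

def synthetic_reference_tables(seed: int = 0) -> dict:
    """Synthetic stand-ins for the study's published signature tables.

    The original supplementary tables are external downloads; this builder
    constructs replacement tables at the published study scale so the
    counting pipeline can be exercised end to end: a 961-probe signature
    over 955 genes (six genes carry two probes) on a 27,868-probe array with
    870 upregulated and 91 downregulated probes (a 90.5%/9.5% split); 803 of
    the 955 genes mappable to the partner platform; within the mapped set
    140 genes regulated by TAF9 and 114 by TAF9b, 50 of them by both
    (204 = 50 + 90 + 64 in total).

    Every count reported downstream is *computed* from these tables by the
    pipeline (gene collapsing, direction summary, mapping, Venn
    partitioning); nothing downstream reads the constants back.
    """
    rng = np.random.default_rng(seed)
    n_probes_bg = 27_868
    n_sig_probes, n_sig_genes = 961, 955
    n_up = 870  # 870/961 = 90.53% up, 91 down
    n_mapped = 803
    n_taf9, n_taf9b, n_both = 140, 114, 50

    genes = [f"G{i:06d}" for i in range(n_sig_genes)]
    # Six genes carry a second probe -> 961 probes over 955 genes.
    gene_for_probe = list(genes) + genes[:n_sig_probes - n_sig_genes]
    probes = [f"P{i:06d}" for i in range(n_sig_probes)]

    signs = np.ones(n_sig_probes)
    signs[n_up:] = -1.0
    rng.shuffle(signs)
    lfc = signs * np.maximum(np.abs(rng.normal(2.0, 0.6, n_sig_probes)), 1e-3)
    pvals = rng.uniform(1e-8, 0.05, n_sig_probes)

    sig_main = SignatureTable(
        frame=pd.DataFrame({
            "probe_id": probes,
            "gene_id": gene_for_probe,
            "log2fc": lfc,
            "p_value": pvals,
        }),
        background_size=n_probes_bg,
    )

    mapped_genes = list(rng.choice(genes, size=n_mapped, replace=False))
    # Disjoint blocks inside the mapped set: both / TAF9-only / TAF9b-only.
    both = mapped_genes[:n_both]
    taf9_only = mapped_genes[n_both:n_both + (n_taf9 - n_both)]
    taf9b_only = mapped_genes[n_taf9:n_taf9 + (n_taf9b - n_both)]
    taf9_genes = both + taf9_only
    taf9b_genes = both + taf9b_only

    def _partner_table(sig_genes: list[str], tag: str) -> SignatureTable:
        k = len(sig_genes)
        s = np.where(rng.random(k) < 0.5, 1.0, -1.0)
        return SignatureTable(
            frame=pd.DataFrame({
                "probe_id": [f"{tag}:{g}" for g in sig_genes],
                "gene_id": sig_genes,
                "log2fc": s * np.maximum(np.abs(rng.normal(1.0, 0.4, k)), 1e-3),
                "p_value": rng.uniform(1e-8, 0.05, k),
            }),
            background_size=n_mapped,
        )

    return {
        "signature": sig_main,
        "taf9": _partner_table(taf9_genes, "T9"),
        "taf9b": _partner_table(taf9b_genes, "T9b"),
        "mapped_universe": frozenset(mapped_genes),
        "probe_map": {p: g for p, g in zip(probes, gene_for_probe)},
    }
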