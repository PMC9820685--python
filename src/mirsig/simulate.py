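"""Synthetic NanoString-style miRNA cohorts with known ground truth.

The default objects emulate the study design this package analyzes: an
nCounter-style panel of 827 endogenous miRNA probes with 5 housekeeping and
6+6 control probes, a cohort of 25 patients contributing 14 primary and 30
brain-metastatic samples (44 in total), and an 11-miRNA differential
signature (5 up, 6 down in metastasis) carried by 10 probes — one probe is
shared by miR-199a-3p and miR-199b-3p, whose mature sequences are identical.

Counts are drawn from a negative-binomial model with additive Poisson
background, a log-normal per-sample library-size factor and a normal
per-patient effect on the log2 scale; see :func:`simulate` for the exact
form. The model is a generator design choice emulating nCounter
over-dispersion, not a claim about the real assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError, EffectConflictError, UnknownMiRNAError
from .io import ExpressionDataset

# Differential signature: direction of change in metastasis relative to
# primary. The five upregulated miRNAs sit close to background in primary
# tissue; the six downregulated ones are abundant in both compartments.
SIGNATURE_UP = (
    "miR-9-5p",
    "miR-129-2-3p",
    "miR-124-3p",
    "miR-219a-5p",
    "miR-219a-2-3p",
)
SIGNATURE_DOWN = (
    "miR-199a-5p",
    "miR-199a-3p",
    "miR-199b-3p",
    "miR-199b-5p",
    "miR-150-5p",
    "miR-142-3p",
)
SHARED_PROBE_MIRNAS = ("miR-199a-3p", "miR-199b-3p")

N_ENDOGENOUS = 827
N_HOUSEKEEPING = 5

_LOW_BASELINE = float(np.log2(20.0))  # near-background in primary tissue
_HIGH_BASELINE = float(np.log2(2000.0))  # abundantly expressed


@dataclass(frozen=True)
class ProbeDefinition:
    probe_id: str
    probe_class: str  # endogenous | housekeeping | positive_control | negative_control
    annotated_mirnas: tuple[str, ...]
    baseline_log2_abundance: float

    def __post_init__(self) -> None:
        if self.probe_class == "endogenous":
            if not self.annotated_mirnas:
                raise DomainError("endogenous probe needs >= 1 annotated miRNA")
        elif self.annotated_mirnas:
            raise DomainError("control probes carry no miRNA annotation")
        if self.baseline_log2_abundance < 0:
            raise DomainError("baseline_log2_abundance must be >= 0")


@dataclass(frozen=True)
class PanelDefinition:
    probes: tuple[ProbeDefinition, ...]

    def __post_init__(self) -> None:
        ids = [p.probe_id for p in self.probes]
        if len(set(ids)) != len(ids):
            raise DomainError("probe_ids must be unique within a panel")

    def probe_info(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_class": [p.probe_class for p in self.probes],
                "annotated_mirnas": [p.annotated_mirnas for p in self.probes],
            },
            index=pd.Index([p.probe_id for p in self.probes], name="probe_id"),
        )

    def baselines(self) -> np.ndarray:
        return np.array([p.baseline_log2_abundance for p in self.probes])

    def mirna_to_probes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for p in self.probes:
            for m in p.annotated_mirnas:
                out.setdefault(m, []).append(p.probe_id)
        return out


@dataclass(frozen=True)
class CohortDesign:
    """Patients and the samples each contributes."""

    patients: tuple[tuple[str, bool, int], ...]  # (patient_id, has_primary, n_met)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_primary(self) -> int:
        return sum(1 for _, has_p, _ in self.patients if has_p)

    @property
    def n_metastatic(self) -> int:
        return sum(n for _, _, n in self.patients)

    @property
    def n_samples(self) -> int:
        return self.n_primary + self.n_metastatic

    def sample_meta(self) -> pd.DataFrame:
        rows = []
        for pid, has_primary, n_met in self.patients:
            if has_primary:
                rows.append((f"{pid}-P", pid, "primary"))
            for j in range(n_met):
                rows.append((f"{pid}-M{j + 1}", pid, "metastasis"))
        df = pd.DataFrame(rows, columns=["sample_id", "patient_id", "tissue_class"])
        return df.set_index("sample_id")


@dataclass(frozen=True)
class PlantedSignature:
    effects: tuple[tuple[str, str, float], ...]  # (mirna, direction, log2fc magnitude)
    low_abundance_in_primary: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for mirna, direction, mag in self.effects:
            if direction not in ("up", "down"):
                raise DomainError(f"bad direction {direction!r} for {mirna}")
            if mag <= 0:
                raise DomainError("log2fc_magnitude must be positive")

    @property
    def mirnas(self) -> tuple[str, ...]:
        return tuple(m for m, _, _ in self.effects)

    def direction_map(self) -> dict[str, str]:
        return {m: d for m, d, _ in self.effects}

    def signed_log2fc(self) -> dict[str, float]:
        return {m: (mag if d == "up" else -mag) for m, d, mag in self.effects}

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m, d, mag) for m, d, mag in self.effects],
            columns=["mirna", "direction", "log2fc_magnitude"],
        )


EMPTY_SIGNATURE = PlantedSignature(effects=())


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the count model; defaults emulate FFPE nCounter data."""

    nb_dispersion: float = 10.0  # negative-binomial size r; var = m + m^2/r
    background_mean: float = 12.0  # Poisson background, also negative controls
    patient_effect_sd: float = 0.25  # log2-scale random patient shift
    librarysize_sd: float = 0.3  # log-normal sd of per-sample scaling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0 or self.background_mean <= 0:
            raise DomainError("nb_dispersion and background_mean must be positive")
        if self.patient_effect_sd < 0 or self.librarysize_sd < 0:
            raise DomainError("standard deviations must be non-negative")


@dataclass
class SyntheticDataset:
    dataset: ExpressionDataset
    signature: PlantedSignature
    scale_factors_true: pd.Series  # per-sample library-size factor L_s
    patient_effects_true: pd.Series = field(default_factory=pd.Series)

    @property
    def counts(self) -> pd.DataFrame:
        return self.dataset.counts

    @property
    def sample_meta(self) -> pd.DataFrame:
        return self.dataset.sample_meta

    def planted_probes(self) -> list[str]:
        """Probe ids annotated to any planted miRNA."""
        mirnas = set(self.signature.mirnas)
        info = self.dataset.probe_info
        return [
            pid
            for pid, mir in info["annotated_mirnas"].items()
            if mirnas & set(mir)
        ]


# -- default objects -----------------------------------------------------------


def build_default_panel() -> PanelDefinition:
    """The default 827-endogenous-probe panel with the 11-miRNA signature.

    Deterministic. Ten probes carry the signature (one shared by
    miR-199a-3p/miR-199b-3p); the remaining 817 endogenous probes get
    synthetic placeholder names and baselines spread over ~log2(32)..log2(4k).
    """
    probes: list[ProbeDefinition] = []
    for m in SIGNATURE_UP:
        probes.append(
            ProbeDefinition(f"probe-{m}", "endogenous", (m,), _LOW_BASELINE)
        )
    shared_done = False
    for m in SIGNATURE_DOWN:
        if m in SHARED_PROBE_MIRNAS:
            if not shared_done:
                probes.append(
                    ProbeDefinition(
                        "probe-miR-199-3p",
                        "endogenous",
                        SHARED_PROBE_MIRNAS,
                        _HIGH_BASELINE,
                    )
                )
                shared_done = True
        else:
            probes.append(
                ProbeDefinition(f"probe-{m}", "endogenous", (m,), _HIGH_BASELINE)
            )
    n_filler = N_ENDOGENOUS - len(probes)
    for i in range(1, n_filler + 1):
        name = f"mir-syn-{i:04d}"
        baseline = 5.0 + 7.0 * ((i * 37) % 100) / 99.0  # deterministic spread
        probes.append(ProbeDefinition(f"probe-{name}", "endogenous", (name,), baseline))
    for i in range(1, N_HOUSEKEEPING + 1):
        probes.append(
            ProbeDefinition(f"HK-{i}", "housekeeping", (), 9.0 + 0.5 * i)
        )
    for i, letter in enumerate("ABCDEF"):
        probes.append(  # geometric ladder of means, factor 4 per step
            ProbeDefinition(f"POS-{letter}", "positive_control", (), 14.0 - 2.0 * i)
        )
    for letter in "ABCDEF":
        probes.append(ProbeDefinition(f"NEG-{letter}", "negative_control", (), 0.0))
    return PanelDefinition(probes=tuple(probes))


def build_default_design() -> CohortDesign:
    """25 patients; P01..P14 have a primary sample; P01..P05 contribute two
    metastatic samples and the rest one, totalling 14 + 30 = 44 samples.

    The per-patient metastatic allocation is a fixed, documented table (any
    allocation summing to 30 would be admissible).
    """
    patients = []
    for i in range(1, 26):
        pid = f"P{i:02d}"
        has_primary = i <= 14
        n_met = 2 if i <= 5 else 1
        patients.append((pid, has_primary, n_met))
    return CohortDesign(patients=tuple(patients))


def default_signature(
    up_magnitude: float = 3.0, down_magnitude: float = 2.0
) -> PlantedSignature:
    """The 11-miRNA planted signature: 5 up, 6 down in metastasis.

    Magnitudes are generator defaults (log2 units), not measured values. The
    five upregulated miRNAs are flagged low-abundance in primary tissue.
    """
    effects = [(m, "up", up_magnitude) for m in SIGNATURE_UP]
    effects += [(m, "down", down_magnitude) for m in SIGNATURE_DOWN]
    return PlantedSignature(
        effects=tuple(effects),
        low_abundance_in_primary=frozenset(SIGNATURE_UP),
    )


# -- count simulation ----------------------------------------------------------


def _planted_delta(
    panel: PanelDefinition, signature: PlantedSignature
) -> dict[str, float]:
    """Signed per-probe log2 shift in metastatic samples; validates effects."""
    probe_map = panel.mirna_to_probes()
    signed = signature.signed_log2fc()
    delta: dict[str, float] = {}
    for mirna, fc in signed.items():
        if mirna not in probe_map:
            raise UnknownMiRNAError(f"signature miRNA {mirna!r} not on panel")
        for probe_id in probe_map[mirna]:
            if probe_id in delta and np.sign(delta[probe_id]) != np.sign(fc):
                raise EffectConflictError(
                    f"probe {probe_id!r} annotated to planted miRNAs of "
                    "opposite directions"
                )
            delta.setdefault(probe_id, fc)
    return delta


def simulate(
    panel: PanelDefinition,
    design: CohortDesign,
    signature: PlantedSignature,
    params: SimulationParams,
) -> SyntheticDataset:
    """Draw a count matrix from the generative model.

    For endogenous and housekeeping probes,

    ``count[p, s] ~ NegBin(mean = L_s * 2**(b_p + u_pat(s) + delta[p, s]),
    size = nb_dispersion) + Poisson(background_mean)``

    where ``b_p`` is the probe baseline, ``u_pat ~ Normal(0,
    patient_effect_sd)`` per patient, ``L_s ~ LogNormal(0, librarysize_sd)``
    per sample, and ``delta`` is the signed planted log2 fold change for
    probes annotated to a planted miRNA in metastatic samples (zero
    otherwise). Positive controls follow the panel's fixed geometric ladder
    of means scaled by ``L_s`` (no patient effect or planted shift);
    negative controls are pure ``Poisson(background_mean)``. A fixed seed
    yields a bit-identical matrix.
    """
    rng = np.random.default_rng(params.seed)
    meta = design.sample_meta()
    n_samples = len(meta)
    probe_info = panel.probe_info()
    n_probes = len(probe_info)
    classes = probe_info["probe_class"].to_numpy()
    baselines = panel.baselines()

    delta_map = _planted_delta(panel, signature)

    patient_ids = [pid for pid, _, _ in design.patients]
    u = rng.normal(0.0, params.patient_effect_sd, size=len(patient_ids))
    u_by_patient = dict(zip(patient_ids, u))
    u_s = np.array([u_by_patient[p] for p in meta["patient_id"]])
    L_s = rng.lognormal(0.0, params.librarysize_sd, size=n_samples)

    is_met = (meta["tissue_class"] == "metastasis").to_numpy()
    delta = np.zeros((n_probes, n_samples))
    for i, probe_id in enumerate(probe_info.index):
        fc = delta_map.get(probe_id)
        if fc:
            delta[i, is_met] = fc

    log2_mean = baselines[:, None] + delta
    endo_hk = np.isin(classes, ["endogenous", "housekeeping"])
    log2_mean[endo_hk] += u_s[None, :]
    mean = L_s[None, :] * np.exp2(log2_mean)

    counts = np.zeros((n_probes, n_samples), dtype=np.int64)
    nb_rows = np.isin(classes, ["endogenous", "housekeeping", "positive_control"])
    r = params.nb_dispersion
    m = mean[nb_rows]
    counts[nb_rows] = rng.negative_binomial(r, r / (r + m)) + rng.poisson(
        params.background_mean, size=m.shape
    )
    neg_rows = classes == "negative_control"
    counts[neg_rows] = rng.poisson(
        params.background_mean, size=(neg_rows.sum(), n_samples)
    )

    counts_df = pd.DataFrame(counts, index=probe_info.index, columns=meta.index)
    ds = ExpressionDataset(counts=counts_df, probe_info=probe_info, sample_meta=meta)
    return SyntheticDataset(
        dataset=ds,
        signature=signature,
        scale_factors_true=pd.Series(L_s, index=meta.index, name="library_size"),
        patient_effects_true=pd.Series(u, index=patient_ids, name="patient_effect"),
    )


def simulate_default(seed: int, signature: PlantedSignature | None = None,
                     params: SimulationParams | None = None) -> SyntheticDataset:
    """Default panel + design + signature at the given seed."""
    if signature is None:
        signature = default_signature()
    if params is None:
        params = SimulationParams(seed=seed)
    else:
        params = replace(params, seed=seed)
    return simulate(build_default_panel(), build_default_design(), signature, params)


# -- fixtures for target scoring and networks ----------------------------------


@dataclass
class TargetFixture:
    """Generated miRNA->gene interactions plus generation-time ground truth.

    ``expected`` holds per-gene event/link counts and absolute-score sums per
    direction group, accumulated while the interactions were drawn, for use
    as an independent oracle.
    """

    interactions: list  # list[TargetInteraction]
    expected: pd.DataFrame


def make_target_fixture(
    signature: PlantedSignature, n_genes: int, seed: int
) -> TargetFixture:
    """Random TargetScan-style interactions over the signature miRNAs.

    The first three genes (cycled if ``n_genes < 3``) cover the patterns
    up-only, down-only and mixed; later genes draw a pattern at random.
    Context scores are negative (TargetScan convention); each selected
    miRNA contributes one or two site-level events.
    """
    from .targets import TargetInteraction

    if n_genes < 1:
        raise DomainError("n_genes must be >= 1")
    dirs = signature.direction_map()
    ups = [m for m, d in dirs.items() if d == "up"]
    downs = [m for m, d in dirs.items() if d == "down"]
    if not ups or not downs:
        raise DomainError("fixture needs both up- and down-group miRNAs")

    rng = np.random.default_rng(seed)
    patterns = ["up_only", "down_only", "mixed"]
    interactions: list[TargetInteraction] = []
    rows = []
    for i in range(n_genes):
        gene = f"GENE{i + 1:04d}"
        pattern = patterns[i] if i < 3 else patterns[rng.integers(0, 3)]
        chosen: list[str] = []
        if pattern in ("up_only", "mixed"):
            k = int(rng.integers(1, min(3, len(ups)) + 1))
            chosen += list(rng.choice(ups, size=k, replace=False))
        if pattern in ("down_only", "mixed"):
            k = int(rng.integers(1, min(3, len(downs)) + 1))
            chosen += list(rng.choice(downs, size=k, replace=False))
        acc = {
            "gene_symbol": gene,
            "n_events_up": 0,
            "n_events_down": 0,
            "n_links_up": 0,
            "n_links_down": 0,
            "sum_up": 0.0,
            "sum_down": 0.0,
        }
        for mirna in chosen:
            group = dirs[mirna]
            acc[f"n_links_{group}"] += 1
            for _ in range(int(rng.integers(1, 3))):
                score = round(float(-rng.uniform(0.02, 0.45)), 4)
                interactions.append(
                    TargetInteraction(
                        mirna=mirna, gene_symbol=gene, context_score=score
                    )
                )
                acc[f"n_events_{group}"] += 1
                acc[f"sum_{group}"] += abs(score)
        rows.append(acc)
    expected = pd.DataFrame(rows).set_index("gene_symbol")
    return TargetFixture(interactions=interactions, expected=expected)


def make_network_fixture(genes: list[str], edge_density: float, seed: int) -> list:
    """Erdős–Rényi-style signed edges among ``genes[:-1]``.

    The last gene of the list is guaranteed isolated (no incident edges), so
    the hub filter always has something to drop. Each realized unordered pair
    gets a random orientation and a random activation/inhibition mode.
    """
    from itertools import combinations

    from .network import RegulatoryEdge

    if len(genes) < 2:
        raise DomainError("need >= 2 genes")
    if not 0.0 <= edge_density <= 1.0:
        raise DomainError("edge_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    edges: list[RegulatoryEdge] = []
    for a, b in combinations(genes[:-1], 2):
        if rng.random() < edge_density or edge_density == 1.0:
            src, dst = (a, b) if rng.random() < 0.5 else (b, a)
            mode = "activation" if rng.random() < 0.5 else "inhibition"
            edges.append(RegulatoryEdge(source=src, target=dst, mode=mode))
    return edges
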