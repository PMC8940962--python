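"""Synthetic inputs emulating a vertically sectioned hypersaline mat study.

The generators reproduce the *design* of the field campaign — seven 1-mm
layers cut from three replicate cores assayed for nine qPCR/RT-qPCR markers
on DNA and cDNA templates, a four-layer metagenome gene catalog with
nitrogen-pathway KO annotations and depth-structured coverage, and HAO-family
protein sequences carrying either the active-site cross-linking tyrosine
(oxidative HAO) or the tryptophan + methionine motif (εHao) — with known
ground truth, so every downstream stage can be exercised and checked at desk
scale. Values are synthetic; magnitudes follow the published depth profiles.

Noise is lognormal (Normal on the log10 scale) for both copy numbers and
coverage, since the emulated quantities span many orders of magnitude. Each
output table draws from its own RNG stream, seeded from ``SimConfig.seed``
by a stable offset, so adding a table never perturbs existing ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nitrogen_coverage import CATEGORIES, NITROGEN_KO_MAP

DEFAULT_MARKERS = (
    "Bacteria-16S",
    "Archaea-16S",
    "nifH",
    "Archaeal-amoA",
    "Bacterial-amoA",
    "Nitrospira-nxrB",
    "nosZ",
    "nirS",
    "Planctomycetes-16S",
)

# Per-marker depth profile of true mean log10 DNA copies per g of mat:
# (low log10, high log10, peak layer), mean(layer) = lo + (hi-lo) *
# exp(-(layer-peak)^2 / (2 * 1.5^2)). Ranges and peak layers follow the
# published per-g profiles; the Gaussian bump shape is a modeling choice.
MARKER_DNA_PROFILES: dict[str, tuple[float, float, float]] = {
    "Bacteria-16S": (5.0, 9.0, 2.5),
    "Archaea-16S": (6.0, 8.0, 4.0),
    "nifH": (8.0, 10.5, 2.0),
    "Archaeal-amoA": (4.0, 4.9, 3.0),
    "Bacterial-amoA": (4.0, 6.6, 3.0),
    "Nitrospira-nxrB": (5.0, 7.0, 3.0),
    "nosZ": (3.8, 5.4, 3.0),
    "nirS": (5.3, 7.6, 3.0),
    "Planctomycetes-16S": (4.5, 6.2, 3.0),
}
# (peak cDNA/DNA ratio, layer of peak expression); off-peak ratio floor 0.2.
MARKER_RATIO_PROFILES: dict[str, tuple[float, float]] = {
    "Bacteria-16S": (1.5, 3.0),
    "Archaea-16S": (1.5, 3.0),
    "nifH": (2.0, 3.0),
    "Archaeal-amoA": (1.7, 3.0),
    "Bacterial-amoA": (3.3, 3.0),
    "Nitrospira-nxrB": (1.3, 4.0),
    "nosZ": (7.0, 4.0),
    "nirS": (5.0, 4.0),
    "Planctomycetes-16S": (2.0, 4.0),
}

# Published unique-gene inventory of the nitrogen pathway (per-symbol counts).
# The assimilatory split nirA/narB/NRT is not published; 9+4+2 sums to the
# reported category total of 15.
PATHWAY_FIXTURE_COUNTS: dict[str, int] = {
    "nifD": 17, "nifH": 22, "nifK": 21,
    "nirA": 9, "narB": 4, "NRT": 2,
    "nrfA": 26, "nrfH": 12,
    "hao": 52,
    "hcp": 121,
    "narG/narZ/nxrA": 4, "narH/narY/nxrB": 6, "narI/narV": 31,
    "napA": 7, "napB": 5, "nirK": 2, "nirS": 1,
    "norB": 6, "norC": 1, "nosZ": 6,
}

DEFAULT_GENES_PER_CATEGORY: dict[str, int] = {
    "nitrogen fixation": 60,
    "assimilatory nitrate reduction": 15,
    "DNRA": 38,
    "hydroxylamine dehydrogenase": 52,
    "hydroxylamine reductase": 121,
    "denitrification": 69,
    "background": 300,
}

# log10 coverage change per mm of depth, by category. Signs follow the
# published depth trends (fixation/assimilation surface-maximal, DNRA and
# hydroxylamine metabolism increasing with depth).
DEFAULT_DEPTH_TREND: dict[str, float] = {
    "nitrogen fixation": -0.144,
    "assimilatory nitrate reduction": -0.16,
    "DNRA": 0.20,
    "hydroxylamine dehydrogenase": 0.12,
    "hydroxylamine reductase": 0.10,
    "denitrification": 0.08,
    "background": 0.0,
}

_SYMBOL_TO_KO = {sym: ko for ko, (sym, _) in NITROGEN_KO_MAP.items()}
_CATEGORY_SYMBOLS: dict[str, list[str]] = {}
for _ko, (_sym, _cat) in NITROGEN_KO_MAP.items():
    _CATEGORY_SYMBOLS.setdefault(_cat, []).append(_sym)

_TAXA = (
    "Cyanobacteria", "Campylobacterota", "Planctomycetes",
    "Proteobacteria", "Chloroflexi", "unclassified",
)

_AA20 = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic mat."""

    seed: int = 0
    n_layers: int = 7
    n_replicates: int = 3
    markers: tuple = DEFAULT_MARKERS
    n_metagenome_layers: int = 4
    n_genes_per_category: dict = field(
        default_factory=lambda: dict(DEFAULT_GENES_PER_CATEGORY)
    )
    depth_trend: dict = field(default_factory=lambda: dict(DEFAULT_DEPTH_TREND))
    noise_sd_log10: float = 0.15
    detection_limit: float = 10.0  # copies per reaction
    n_oxidative_hao: int = 5
    n_epsilon_hao: int = 15
    hao_mutation_rate: float = 0.05

    def __post_init__(self):
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        if self.noise_sd_log10 < 0:
            raise ValueError("noise_sd_log10 must be >= 0")
        if self.detection_limit <= 0:
            raise ValueError("detection_limit must be positive")
        if not (0 <= self.hao_mutation_rate < 1):
            raise ValueError("hao_mutation_rate must be in [0, 1)")
        unknown = set(self.n_genes_per_category) - set(CATEGORIES) - {"background"}
        if unknown:
            raise ValueError(f"unknown gene categor(ies): {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Truth entries every generated record traces back to."""

    qpcr_mean_log10: pd.DataFrame | None = None  # marker, layer, template, mean_log10
    gene_trend: dict | None = None               # category -> slope (log10 per mm)
    hao_labels: dict | None = None               # query id -> class label


def _rng(config: SimConfig, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), offset])


def _dna_mean_log10(marker: str, layer: int) -> float:
    lo, hi, peak = MARKER_DNA_PROFILES.get(marker, (5.0, 7.0, 3.0))
    return lo + (hi - lo) * np.exp(-((layer - peak) ** 2) / (2 * 1.5**2))


def _ratio(marker: str, layer: int) -> float:
    rmax, peak = MARKER_RATIO_PROFILES.get(marker, (1.0, 3.0))
    return 0.2 + (rmax - 0.2) * np.exp(-((layer - peak) ** 2) / (2 * 1.0**2))


def simulate_qpcr_panel(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the full marker x layer x replicate x template qPCR panel.

    Copies are drawn as 10^(true mean log10 + Normal(0, noise_sd_log10));
    records under the detection limit are flagged ``below_lod`` but kept.
    """
    rng = _rng(config, 1)
    mat_mass_g, na_mass_ng = 0.25, 400.0
    rows, truth_rows = [], []
    for marker in config.markers:
        for layer in range(1, config.n_layers + 1):
            dna_mu = _dna_mean_log10(marker, layer)
            means = {"DNA": dna_mu, "cDNA": dna_mu + np.log10(_ratio(marker, layer))}
            for template in ("DNA", "cDNA"):
                truth_rows.append((marker, layer, template, means[template]))
                for rep in range(1, config.n_replicates + 1):
                    per_g = 10 ** (
                        means[template] + rng.normal(0.0, config.noise_sd_log10)
                    )
                    raw = per_g * mat_mass_g
                    rows.append(
                        (marker, layer, rep, template, raw, mat_mass_g, na_mass_ng,
                         raw < config.detection_limit)
                    )
    df = pd.DataFrame(
        rows,
        columns=["marker", "layer", "replicate", "template", "raw_copies",
                 "mat_mass_g", "na_mass_ng", "below_lod"],
    )
    truth = GroundTruth(
        qpcr_mean_log10=pd.DataFrame(
            truth_rows, columns=["marker", "layer", "template", "mean_log10"]
        )
    )
    return df, truth


def simulate_gene_catalog_and_coverage(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a KO-annotated gene catalog with depth-structured coverage.

    Each gene gets one KO consistent with its category (background genes get
    out-of-vocabulary KOs so that nitrogen filtering is nontrivial); coverage
    across the metagenome layers follows the category's depth trend with
    multiplicative lognormal noise.
    """
    rng = _rng(config, 2)
    ann_rows, cov_rows = [], []
    gene_idx = 0
    for category, n_genes in config.n_genes_per_category.items():
        if category == "background":
            symbols = None
        else:
            symbols = _CATEGORY_SYMBOLS[category]
        slope = config.depth_trend.get(category, 0.0)
        for i in range(n_genes):
            gene_id = f"gene_{gene_idx:05d}"
            gene_idx += 1
            if symbols is None:
                symbol = f"bg{i:04d}"
                ko = f"K9{rng.integers(0, 10000):04d}"
            else:
                symbol = symbols[int(rng.integers(len(symbols)))]
                ko = _SYMBOL_TO_KO[symbol]
            taxon = _TAXA[int(rng.integers(len(_TAXA)))]
            ann_rows.append((gene_id, ko, symbol, category, taxon))
            base = 10 ** rng.normal(1.0, 0.3)
            for layer in range(1, config.n_metagenome_layers + 1):
                cov = base * 10 ** (
                    slope * (layer - 1) + rng.normal(0.0, config.noise_sd_log10)
                )
                cov_rows.append((gene_id, layer, cov))
    ann = pd.DataFrame(ann_rows, columns=["gene_id", "ko", "symbol", "category", "taxon"])
    cov = pd.DataFrame(cov_rows, columns=["gene_id", "layer", "coverage"])
    truth = GroundTruth(gene_trend=dict(config.depth_trend))
    return ann, cov, truth


def generate_hao_proteins(config: SimConfig) -> tuple[list, GroundTruth]:
    """Generate query HAO proteins of known class from the packaged templates.

    Oxidative-class sequences keep the tyrosine at the anchor-equivalent
    position; epsilon-class keep the tryptophan there and the methionine
    eight ungapped residues before it. All other positions mutate i.i.d. at
    ``hao_mutation_rate``.
    """
    from .hao_motif_phylo import load_packaged_reference, map_anchor_column

    rng = _rng(config, 3)
    ref = load_packaged_reference()
    col = map_anchor_column(ref)  # 1-based alignment column

    def template_and_protected(row_id):
        aligned = dict(ref.rows)[row_id]
        ungapped = aligned.replace("-", "")
        # ungapped index (0-based) of the anchor-column residue in this row
        idx = len(aligned[:col].replace("-", "")) - 1
        return ungapped, idx

    oxi_row = ref.anchor_ref
    eps_row = next(rid for rid, _ in ref.rows if ref.class_labels[rid] == "epsilonHao")
    oxi_tpl, oxi_idx = template_and_protected(oxi_row)
    eps_tpl, eps_idx = template_and_protected(eps_row)

    def mutate(tpl, protected):
        out = list(tpl)
        for i in range(len(out)):
            if i in protected:
                continue
            if rng.random() < config.hao_mutation_rate:
                choices = _AA20[_AA20 != out[i]]
                out[i] = str(choices[int(rng.integers(len(choices)))])
        return "".join(out)

    records, labels = [], {}
    for i in range(config.n_oxidative_hao):
        qid = f"query_oxi_{i:02d}"
        records.append((qid, mutate(oxi_tpl, {oxi_idx})))
        labels[qid] = "oxidative-HAO-like"
    for i in range(config.n_epsilon_hao):
        qid = f"query_eps_{i:02d}"
        records.append((qid, mutate(eps_tpl, {eps_idx, eps_idx - 8})))
        labels[qid] = "epsilonHao-like"
    return records, GroundTruth(hao_labels=labels)


def make_env_fixture() -> pd.DataFrame:
    """Seven-layer porewater/oxygen depth profile fixture.

    Oxygen is a diel range (µM); layers where it was not detectable are
    encoded as absent (NaN). Nutrient columns carry the layer means and
    standard deviations (µM).
    """
    rows = [
        # layer, o2_min, o2_max, nh4, nh4_sd, no3, no3_sd, po4, po4_sd
        (1, 200.0, 800.0, 34.1, 12.8, 33.2, 10.9, 5.5, 1.3),
        (2, 0.0, 1200.0, 58.6, 27.5, 30.3, 2.8, 2.6, 0.3),
        (3, 0.0, 200.0, 110.8, 62.4, 30.5, 3.7, 3.1, 0.7),
        # Layer 4: oxygen only detectable under very high light
        (4, 0.0, np.nan, 109.2, 52.7, 30.5, 3.7, 3.1, 0.7),
        (5, np.nan, np.nan, 116.5, 69.0, 30.6, 10.9, 2.7, 1.2),
        (6, np.nan, np.nan, 115.6, 38.4, 30.6, 10.9, 2.7, 1.2),
        (7, np.nan, np.nan, 124.0, 34.3, 26.05, 5.2, 4.6, 0.7),
    ]
    return pd.DataFrame(
        rows,
        columns=["layer", "o2_min_um", "o2_max_um", "nh4_um", "nh4_sd_um",
                 "no3_um", "no3_sd_um", "po4_um", "po4_sd_um"],
    )


def make_pathway_fixture() -> pd.DataFrame:
    """Worked-example annotation table with the published per-symbol counts.

    One row per unique catalog gene; counts per symbol reproduce the
    reported nitrogen-pathway inventory (355 genes over six categories).
    """
    sym_to_cat = {sym: cat for _, (sym, cat) in NITROGEN_KO_MAP.items()}
    rows = []
    idx = 0
    for symbol, count in PATHWAY_FIXTURE_COUNTS.items():
        ko = _SYMBOL_TO_KO[symbol]
        cat = sym_to_cat[symbol]
        for _ in range(count):
            rows.append((f"fx_{idx:04d}", ko, symbol, cat, "unclassified"))
            idx += 1
    return pd.DataFrame(rows, columns=["gene_id", "ko", "symbol", "category", "taxon"])
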