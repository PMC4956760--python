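"""End-to-end orchestration: phantom -> cube -> fit -> calibrate -> quantify
-> cluster statistics. This is the path the analysis drivers, the CLI and
the acceptance checks all share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .fitting import FitModel, FitResult, IntensityMaps, fit_cube, fit_spectrum
from .forward import (InstrumentConfig, MapCube, SampleModel,
                      simulate_cube, simulate_reference_spectrum)
from .mining import (ClusterStats, build_feature_matrix, cluster_statistics,
                     correlation_matrix, kmeans_cluster, match_clusters, pca)
from .phantom import (CELL_LABELS, EXTRACELL_LABELS, Geometry, GroundTruthMaps,
                      Label, TissueProfile, assign_concentrations,
                      generate_label_map, make_reference_standard)
from .quantify import (SensitivityTable, calibrate_sensitivity, dl_table,
                       quantify_map)


def default_reference():
    """Bovine-liver-like standard with the embedded certified values."""
    return make_reference_standard(C.NIST_1577C, thickness_um=100.0, density=1.0)


@dataclass
class PipelineResult:
    truth: GroundTruthMaps
    cube: MapCube
    intensity: IntensityMaps
    ref_fit: FitResult
    sens: SensitivityTable
    conc: dict                         # element -> quantified wt-fraction map
    dl: object                         # DataFrame indexed by element
    cluster_stats: ClusterStats | None = None
    stroma_cell_pt_ratio: float | None = None
    extras: dict = field(default_factory=dict)

    def map_mean(self, element: str) -> float:
        return float(self.conc[element].mean())


def build_phantom(profile: TissueProfile | str = "normothermic",
                  shape=(128, 128), pixel_size_nm: float = 50.0,
                  geometry: Geometry | None = None, seed: int = 0) -> GroundTruthMaps:
    if isinstance(profile, str):
        profile = TissueProfile.preset(profile)
    lm = generate_label_map(shape, pixel_size_nm, geometry, seed=seed)
    return assign_concentrations(lm, profile, seed=seed + 1)


def run_pipeline(profile: TissueProfile | str = "normothermic",
                 shape=(128, 128), seed: int = 0,
                 instrument: InstrumentConfig | None = None,
                 sample: SampleModel | None = None,
                 dwell_s: float = 0.1, ref_live_time_s: float = 500.0,
                 geometry: Geometry | None = None,
                 with_mining: bool = True, k: int = 3) -> PipelineResult:
    """Full synthetic experiment at one tissue position.

    Seeds for the phantom, the scan and the reference acquisition are
    derived from ``seed`` so one integer reproduces the whole run.
    """
    instrument = instrument or InstrumentConfig()
    sample = sample or SampleModel()

    truth = build_phantom(profile, shape, geometry=geometry, seed=seed)
    cube = simulate_cube(truth, instrument, sample, dwell_s, seed=seed + 10_000)

    intensity = fit_cube(cube)

    ref = default_reference()
    ref_spec = simulate_reference_spectrum(ref, instrument, ref_live_time_s,
                                           seed=seed + 20_000)
    ref_model = FitModel(instrument=instrument,
                         sample=SampleModel.from_reference(ref))
    ref_fit = fit_spectrum(ref_spec, ref_model)

    sens = calibrate_sensitivity(ref_fit, ref, ref_live_time_s,
                                 instrument=instrument, target_sample=sample)
    conc = quantify_map(intensity, sens, dwell_s)

    # per-pixel backgrounds at the dwell time for uncertified-element DLs
    sample_bg = {el: float(np.mean(intensity.background[el]))
                 for el in intensity.background}
    dls = dl_table(ref_fit, ref, ref_live_time_s, dwell_s, sens=sens,
                   sample_backgrounds=sample_bg)

    result = PipelineResult(truth, cube, intensity, ref_fit, sens, conc, dls)

    labels = truth.label_map.labels
    stats = cluster_statistics(labels, conc)
    result.cluster_stats = stats
    if "Pt" in conc and truth.profile.cbar.get("Pt", 0) > 0:
        result.stroma_cell_pt_ratio = stats.ratio(
            [int(l) for l in EXTRACELL_LABELS], [int(l) for l in CELL_LABELS], "Pt")

    if with_mining:
        feats = build_feature_matrix({el: intensity.intensity[el]
                                      for el in ("P", "S", "Zn", "Pt")
                                      if el in intensity.intensity})
        cm = kmeans_cluster(feats, k=k, seed=seed + 30_000)
        groups = np.select(
            [np.isin(labels, [int(l) for l in CELL_LABELS]),
             labels == int(Label.PT_STRING)],
            [1, 2], default=0)
        mapping, agreement = match_clusters(cm.labels, groups)
        corr, _ = correlation_matrix(conc)
        result.extras.update(cluster_map=cm, cluster_truth_agreement=agreement,
                             cluster_mapping=mapping, correlations=corr,
                             pca=pca(feats))
    return result
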