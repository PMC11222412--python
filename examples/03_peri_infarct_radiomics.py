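"""Extract the 513-feature radiomics vector per image channel.

The peri-infarct ROI is the DWI lesion dilated outward (in-plane pixels for
SWI, millimetres for CTP). Each channel yields 57 base features (18
first-order + 24 co-occurrence + 15 run-length) on the original image and
on 8 wavelet sub-bands: 57 x 9 = 513; SWI + three perfusion maps = 2052.
"""

from srstroke import SimulationConfig, extract_case_features, generate_patient
from srstroke.pipeline import RunConfig, build_case_rois
from srstroke.synthetic_data import patient_rng

config = RunConfig(sim=SimulationConfig(seed=3))
patient = generate_patient(config.sim, label=1, rng=patient_rng(3, 0))
rois = build_case_rois(patient.dwi_mask, config)

fv = extract_case_features(patient, rois, modalities=("SWI", "CTP"),
                           config=config.radiomics,
                           frame_interval_s=config.sim.frame_interval_s)
print(f"feature vector length: {len(fv.values)}")
channels = sorted({n.split(".")[0] for n in fv.names})
print("channels:", channels)
print("first five names:", list(fv.names[:5]))
mean_ttp = fv.values[fv.names.index("TTP.original.firstorder.mean")]
print(f"mean peri-infarct TTP feature: {mean_ttp:.2f} s")
# 2052 named, finite features per case; the TTP mean is one of the
# strongest single discriminators between reversal and enlargement.
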