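"""Self-self dye-balance test: the first validation design of the platform.

The same pooled RNA is labeled with both dyes and co-hybridized on three
subarrays. After LOWESS dye correction, a one-sample moderated t-test of M
against 0 should find no biological probe significant; spike-in controls
carry defined inter-dye ratios and are expected to light up.
"""

from carpoligo import normalize as norm
from carpoligo import pipeline, synthetic

layout, truth, scans = synthetic.preset_selfself(n_arrays=3, seed=42)
m = pipeline.corrected_m_matrix(scans)
classes = pipeline.feature_class_map(next(iter(scans.values())))
res, sig = norm.dye_balance_contrast(m, classes, criterion="raw_p")

print(f"features tested      : {len(res.table)} on {m.shape[1]} self-self arrays")
print(f"significant features : {len(sig)} (|FC| >= 2, p < 0.05)")
print("  by class:", sig["feature_class"].value_counts().to_dict())
bio = classes.reindex(res.table.index).isin(["biological", "replicate"])
frac = (res.table.loc[bio, "p_value"] < 0.05).mean()
print(f"biological p<0.05 fraction: {frac:.3f} (nominal 0.05)")
print()
print("Significant calls fall in control classes (spike-ins with real dye")
print("ratios; corner markers at the noisy detection floor). No systematic")
print("dye bias on biological probes means balanced labeling.")
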