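"""Technical reproducibility of RNA isolation: the second validation design.

Two independent isolations of the same pool, each hybridized on eight
single-channel arrays. Twelve probes are shifted by +1.23 log2 units in
isolation 2 (the regime reported for the real platform); the moderated-t
contrast should recover them with few false positives.
"""

from carpoligo import normalize as norm
from carpoligo import pipeline, synthetic

_, _, scans, shifted = synthetic.preset_two_isolations(seed=42)
em = pipeline.single_channel_normalize(pipeline.processed_signal_matrix(scans))
classes = pipeline.feature_class_map(next(iter(scans.values())))
bio = classes.reindex(em.values.index).isin(["biological", "replicate"])
em.values = em.values.loc[bio]

iso1 = em.values[[c for c in em.values.columns if c.startswith("iso1")]]
iso2 = em.values[[c for c in em.values.columns if c.startswith("iso2")]]
res = norm.isolation_contrast(iso1, iso2, criterion="raw_p")

hits = set(res.table.index[res.table["significant"]])
recovered = hits & set(shifted)
print(f"probes tested      : {len(res.table)} (8 vs 8 arrays)")
print(f"injected shifts    : {len(shifted)} probes at +1.23 log2")
print(f"recovered          : {len(recovered)}/{len(shifted)} (|FC| >= 2, p < 0.05)")
print(f"false positives    : {len(hits - set(shifted))}")
print(
    "mean logFC of hits : "
    f"{res.table.loc[sorted(recovered), 'logFC'].mean():+.2f} (truth +1.23)"
)
print()
print("Recovering >= 10/12 shifted probes with ~zero false positives shows")
print("the pipeline resolves isolation-scale technical differences.")
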