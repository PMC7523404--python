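"""From raw wells to dCq(w): efficiency weighting and normalization.

Each measurement contributes log10(E) * Cq; the gene of interest is then
normalized against the mean of the reference genes within the same sample.
"""

from commonbase import WellRecord, delta_cq, weighted_cq

wells = [
    WellRecord("plant_1", "GOI", "target", cq=24.1, efficiency=1.92),
    WellRecord("plant_1", "EF1a", "reference", cq=20.3, efficiency=1.95),
    WellRecord("plant_1", "GAPDH", "reference", cq=21.0, efficiency=1.88),
]

goi = weighted_cq(wells[0])
refs = [weighted_cq(w) for w in wells[1:]]
for w, rec in zip([goi, *refs], wells):
    print(f"{rec.gene:6s} Cq={rec.cq:5.1f} E={rec.efficiency:.2f} -> Cq(w)={w.value:.4f}")

sample = delta_cq(goi, refs)
print(
    f"dCq(w) for {sample.sample_id} = {sample.value:.4f}"
    f" (normalized against {sample.n_refs} reference genes)"
)
# A positive dCq(w) means the target amplifies later than the references,
# i.e. lower expression of the gene of interest.
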