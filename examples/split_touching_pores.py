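"""Split fused pore pairs with the distance-transform watershed.

Plants ten pairs of radius-8 disks joined by narrow necks among twenty
ordinary pores, then runs the watershed on the true pore mask: each pair
should come apart into two labels along the neck.
"""

from hydropore import PhantomSpec, generate_phantom, watershed_split

spec = PhantomSpec(seed=21, n_pores=20, fused_pairs=10, allow_touching=True)
image, truth = generate_phantom(spec)

labels = watershed_split(truth.labels > 0, max_threshold=0.05)
pair_pores = truth.pores[spec.n_pores:]
split = 0
for a, b in zip(pair_pores[0::2], pair_pores[1::2]):
    la = labels[round(a.center_row), round(a.center_col)]
    lb = labels[round(b.center_row), round(b.center_col)]
    split += int(la > 0 and lb > 0 and la != lb)

print(f"planted objects: {len(truth.pores)} pores, of which {2 * 10} form fused pairs")
print(f"watershed labels: {labels.max()}")
print(f"pairs split into two pores: {split}/10")
# the 0.05 cut keeps only distance-transform maxima whose dynamics
# exceed 5% of the global maximum, so each fused pair contributes two
# markers (one per disk centre) and is cut at the neck.
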