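"""Encoding one sequence into the 239-feature vector, block by block.

Prints the block sizes and a few interpretable entries: alanine
composition, the helix/sheet/coil content, and a physico-chemical mean.
"""

import submitoloc as sm

sequence = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALPDAQ"
vector = sm.encode(sequence)
names = sm.feature_names()

print(f"total features: {len(vector.values)}")
for block in sm.BLOCK_LAYOUT:
    print(f"  {block}: {len(vector.block(block))}")

idx = {name: i for i, name in enumerate(names)}
print(f"\ncomposition of A: {vector.values[idx['ccd.comp.A']]:.4f} "
      f"(count {sequence.count('A')} / length {len(sequence)})")
h, e, c = (vector.values[idx[f'sse.content.{s}']] for s in 'HEC')
print(f"secondary-structure content: helix {h:.2f}, sheet {e:.2f}, coil {c:.2f}")
kd = vector.values[idx['physchem.hydropathy_kyte_doolittle']]
print(f"mean Kyte-Doolittle hydropathy: {kd:.3f} (negative = hydrophilic)")
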