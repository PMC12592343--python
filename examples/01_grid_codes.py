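"""Hierarchical quadrant codes: encode, decode, and spatial locality.

Builds the full 64x64 store grid and shows how cell coordinates map to
6-character location codes whose shared prefixes imply spatial proximity.
"""

from storeflow import GridSpec, decode_code, encode_cell, prefix_region, validate_code

grid = GridSpec.full()  # 64x64 cells, depth 6, 0.25 m cells

code = encode_cell(41, 22, grid)
print(f"cell (41, 22)  ->  code {code!r}")
print(f"code {code!r}  ->  cell {decode_code(code, grid)}")

# prefixes name quadtree squares: the longer the shared prefix, the closer
# two locations are guaranteed to be
for plen in (1, 3, 5):
    box = prefix_region(code[:plen], grid)
    side = box[2] - box[0] + 1
    print(f"prefix {code[:plen]!r:9} -> {side}x{side}-cell square {box}")

print("well-formed:", validate_code("bgjoqw", grid))
print("malformed:  ", validate_code("uqmiea", grid), "(letters in wrong level blocks)")
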