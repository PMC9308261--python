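"""Map a quality line into the compact symbol alphabet and invert it.

Runs of the modal score C collapse to one symbol (length + 200); near-C
pairs and triples pack into one symbol; anything far from C stays a
singleton (score - 32).  The mapping is exactly invertible.
"""

from qsarc import MapperParams, map_line, modal_score, unmap_line
from qsarc.qio import QualityLine

line = QualityLine(1, "FFFFFFFF" + chr(71) + chr(72) + chr(68) + chr(69) + chr(70) + chr(40))
C = modal_score([line])
params = MapperParams(C)
symbols = map_line(line, params)

print(f"quality line ({len(line)} scores): {line.scores!r}")
print(f"modal score C: {C} ({chr(C)!r})")
print(f"mapped symbols ({symbols.size}): {symbols.tolist()}")
print("  208     = run of 8 copies of C")
print("  308     = pair (C+1, C+2) packed above C")
print("  164     = triple (C-2, C-1, C) packed below C")
print("  8       = lone far-from-C score, 40 - 32")
print(f"inverse restores the line: {unmap_line(symbols, params) == line.scores}")
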