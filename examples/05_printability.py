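"""Filament and pore quality metrics for printed constructs.

Diffusion rate compares filament width with the nozzle diameter;
circularity and printability score pore shape (a perfect square pore has
Pr = 1); the gelatin/(alginate x TO-NFC) ratio tracks shape fidelity
across formulations (lower is better).
"""

from bioinkflow.datasets import CANONICAL_SYSTEMS
from bioinkflow.printability import (
    FilamentMeasurement,
    PoreMeasurement,
    circularity,
    diffusion_rate,
    gelatin_ratio,
    printability,
    truncate2,
)

filament = FilamentMeasurement(FW=0.58, ND=0.41)
print(f"diffusion rate: {diffusion_rate(filament):.1f}%")

pore = PoreMeasurement(L=3.8, Aa=0.82)
print(f"circularity:  {circularity(pore):.3f}")
print(f"printability: {printability(pore):.3f}")

print("\ngelatin/(alginate x TO-NFC) per composition (lower = better fidelity):")
for comp, _, _ in CANONICAL_SYSTEMS:
    print(f"  {comp.label:<16} {truncate2(gelatin_ratio(comp)):.2f}")
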