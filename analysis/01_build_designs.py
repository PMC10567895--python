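#!/usr/bin/env python
"""Enumerate the DSLR and smartphone acquisition designs.

Writes the two design matrices under results/ and reports the photograph
counts implied by the protocol: with three full-frame bodies, five lens
configurations each (three primes plus a zoom at both focal-length extremes),
six distances, two views and duplicate exposures, each participant sits for
120 photographs per body and 360 in total.  The smartphone arm adds 304
photographs per participant (five back cameras at eight distances, four
front cameras at nine, same views and duplicates).
"""

from pathlib import Path

from facefd import build_dslr_design, build_smartphone_design
from facefd.io import design_to_frame, write_table

OUT = Path(__file__).resolve().parent.parent / "results"
N_PARTICIPANTS = 10

dslr = build_dslr_design(N_PARTICIPANTS)
phone = build_smartphone_design(
    N_PARTICIPANTS,
    # two participants each miss one back camera, as in the study design
    dropouts=[(9, "Oppo A57|back"), (10, "iPhone XR|back")],
)

write_table(OUT / "design_dslr.csv", design_to_frame(dslr))
write_table(OUT / "design_smartphone.csv", design_to_frame(phone))

per_body = len([r for r in dslr if r.camera_name.startswith("Canon EOS 6D|")]) // N_PARTICIPANTS
print(f"DSLR design: {len(dslr)} rows for {N_PARTICIPANTS} participants "
      f"({per_body} per body per participant, {len(dslr) // N_PARTICIPANTS} per participant)")
print(f"smartphone design: {len(phone)} rows "
      f"({(5 * 8 + 4 * 9) * 4} per complete participant, minus 2 dropout blocks of 32)")
print(f"wrote {OUT / 'design_dslr.csv'} and {OUT / 'design_smartphone.csv'}")
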