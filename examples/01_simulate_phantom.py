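"""Simulate a two-scanner travelling-subject phantom and inspect its features.

Builds one synthetic subject, renders it under the source and target
protocols (which differ in gradient directions, a global gain, an
order-wise SH attenuation and Rician noise), and prints the tissue-wise
FA/MD/R0/R2 of both acquisitions.  The printed shift between scanners is
the systematic effect that the harmonisers in the later examples remove.
"""

import numpy as np

from dmriharm import dti, phantom, rish

anat = phantom.make_subject(seed=7)
for name, proto in phantom.DEFAULT_PROTOCOLS.items():
    stack = phantom.render_acquisition(anat, proto, seed=1)
    mask, labels, _ = phantom.anatomy_on_grid(anat, proto)
    tensors = dti.fit_wlls(stack, mask)
    fa, md = dti.fa_map(tensors), dti.md_map(tensors)
    maps = rish.rish_maps(stack, mask)
    wm = np.isin(labels, phantom.WM_LABELS) & mask
    print(f"\n{name} scanner (gain {proto.gain}, order attenuation {proto.order_atten}):")
    print(f"  white matter: FA {fa[wm].mean():.3f}  MD {md[wm].mean():.2e} mm^2/s"
          f"  R0 {np.nanmean(maps[0][wm]):.3f}  R2 {np.nanmean(maps[2][wm]):.4f}")

print(
    "\nThe target scanner's attenuation (a0, a2, a4) lowers R0 (a0^2), R2 "
    "(a2^2) and FA, and shifts MD via the baseline-relative signal level; "
    "those are the systematic differences a harmoniser must learn."
)
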