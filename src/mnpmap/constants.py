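"""Physical constants (SI units throughout the package)."""

import math

#: Vacuum magnetic permeability [Wb/(A*m)] = [T*m/A].
MU0 = 4.0e-7 * math.pi
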