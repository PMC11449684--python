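"""Evaluate the nine activation functions and verify the core identity.

Prints each function's value and derivative at a few points, then
checks numerically that the rectified softsign equals the softsign
composed with a ReLU in either order.
"""

import numpy as np

from actsign import ACTIVATION_NAMES, ActivationSpec, activate, activate_grad

points = [-3.0, -1.0, 0.0, 1.0, 3.0]
print(f"{'function':<20}" + "".join(f"{x:>9}" for x in points))
for name in ACTIVATION_NAMES:
    spec = ActivationSpec(name)
    vals = [activate(spec, x) for x in points]
    print(f"{name:<20}" + "".join(f"{v:>9.4f}" for v in vals))

print("\nderivatives at the same points:")
for name in ACTIVATION_NAMES:
    spec = ActivationSpec(name)
    grads = [activate_grad(spec, x) for x in points]
    print(f"{name:<20}" + "".join(f"{g:>9.4f}" for g in grads))

# the proposed function is softsign∘relu == relu∘softsign
grid = np.linspace(-5, 5, 1001)
rs = activate(ActivationSpec("rectified_softsign"), grid)
comp = activate(ActivationSpec("softsign"),
                activate(ActivationSpec("relu"), grid))
print("\nmax |rectified_softsign - softsign∘relu| on [-5, 5]:",
      float(np.abs(rs - comp).max()))
print("rectified_softsign stays in [0, 1): min %.4f, max %.6f"
      % (rs.min(), rs.max()))
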