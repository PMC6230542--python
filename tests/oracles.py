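"""Independent closed-form oracles shared by the test modules."""

from pseudoct.nn import NetworkSpec


def closed_form_param_count(spec: NetworkSpec) -> int:
    """Parameter-count oracle: conv weights+biases and batch-norm
    scale/shift, summed over the mirrored encoder-decoder topology."""
    k = spec.kernel_size
    conv = lambda cin, cout: k * k * cin * cout + cout
    bn = lambda c: 2 * c
    total = 0
    in_ch = 1
    for n_conv, f in spec.stages:
        for _ in range(n_conv):
            total += conv(in_ch, f) + bn(f)
            in_ch = f
    in_ch = spec.stages[-1][1]
    for n_conv, f in reversed(spec.stages):
        total += conv(in_ch, f) + bn(f)
        total += (n_conv - 1) * (conv(f, f) + bn(f))
        in_ch = f
    total += conv(spec.stages[0][1], 1)
    return total
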