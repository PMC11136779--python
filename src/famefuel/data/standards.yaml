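# Biodiesel quality limits for the properties this package predicts.
# comparator: ge (value must be >= threshold) or le (value must be <= threshold).
# Seasonal limits give one threshold per season; winter is the stricter one.
# Properties a standard does not regulate are simply absent.
version: 1
standards:
  EN14214:
    aliases: ["EN 14214"]
    limits:
      CN:   {comparator: ge, threshold: 51}
      IV:   {comparator: le, threshold: 120}
      DU:   {comparator: le, threshold: 137}
      OS:   {comparator: ge, threshold: 6}
      FP:   {comparator: ge, threshold: 120}
      CFPP: {comparator: le, seasonal: {summer: 5, winter: -20}}
  ASTM:
    aliases: ["ASTM D6751", "ASTM D97550"]
    limits:
      CN: {comparator: ge, threshold: 47}
      OS: {comparator: ge, threshold: 6}
      FP: {comparator: ge, threshold: 93}
  IS15607:
    aliases: ["IS 15607", "IC15607"]
    limits:
      CN:   {comparator: ge, threshold: 51}
      OS:   {comparator: ge, threshold: 6}
      CFPP: {comparator: le, seasonal: {summer: 18, winter: 6}}
      PP:   {comparator: le, seasonal: {summer: 15, winter: 3}}
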