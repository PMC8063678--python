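<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="320" height="320" viewBox="0 0 320 320">
<circle cx="160" cy="160" r="100" fill="none" stroke="#888888" stroke-width="2"/>
<text x="160" y="156" font-size="12" font-family="sans-serif" text-anchor="middle">pANDgate</text>
<text x="160" y="172" font-size="10" font-family="sans-serif" text-anchor="middle">3000 bp</text>
<path d="M 180.6 62.1 A 100 100 0 0 1 187.9 64" fill="none" stroke="#2e8b57" stroke-width="12"/>
<text x="189.6" y="41.6" font-size="9" font-family="sans-serif" text-anchor="start">pBLind</text>
<path d="M 190.7 64.8 A 100 100 0 0 1 195.1 66.3" fill="none" stroke="#e69f00" stroke-width="12"/>
<text x="200.1" y="44.8" font-size="9" font-family="sans-serif" text-anchor="start">rbs34</text>
<path d="M 196.6 66.9 A 100 100 0 0 1 257.5 182.2" fill="none" stroke="#4169e1" stroke-width="12"/>
<text x="267.9" y="103" font-size="9" font-family="sans-serif" text-anchor="start">RFP</text>
<path d="M 256.9 184.7 A 100 100 0 0 1 251.4 200.7" fill="none" stroke="#cc0000" stroke-width="12"/>
<text x="275.3" y="200" font-size="9" font-family="sans-serif" text-anchor="start">L3S2P21</text>
<path d="M 73.5 210.2 A 100 100 0 0 1 85.7 93.1" fill="none" stroke="#707070" stroke-width="12"/>
<text x="38.7" y="147.4" font-size="9" font-family="sans-serif" text-anchor="end">pUC_ori</text>
</svg>
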