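<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="410" height="128" viewBox="0 0 410 128">
<line x1="0" y1="78" x2="410" y2="78" stroke="black" stroke-width="2"/>
<path d="M 17 78 V 60 H 29" fill="none" stroke="blue" stroke-width="2"/><polygon points="29,56 36,60 29,64" fill="blue"/>
<text x="25" y="114" font-size="9" font-family="sans-serif" text-anchor="middle">pBLind</text>
<path d="M 47 78 A 8 8 0 0 1 63 78 Z" fill="#e69f00" stroke="black" stroke-width="1"/>
<polygon points="73,70 89,70 97,78 89,86 73,86" fill="gray" stroke="black" stroke-width="1"/>
<text x="85" y="114" font-size="9" font-family="sans-serif" text-anchor="middle">EL222</text>
<path d="M 115 78 V 64 M 107 64 H 123" fill="none" stroke="#cc0000" stroke-width="2"/>
<path d="M 137 78 V 60 H 149" fill="none" stroke="#2e8b57" stroke-width="2"/><polygon points="149,56 156,60 149,64" fill="#2e8b57"/>
<path d="M 167 78 A 8 8 0 0 1 183 78 Z" fill="#e69f00" stroke="black" stroke-width="1"/>
<polygon points="193,70 209,70 217,78 209,86 193,86" fill="orange" stroke="black" stroke-width="1"/>
<text x="205" y="114" font-size="9" font-family="sans-serif" text-anchor="middle">AraC</text>
<path d="M 235 78 V 64 M 227 64 H 243" fill="none" stroke="#cc0000" stroke-width="2"/>
<path d="M 257 78 V 60 H 269" fill="none" stroke="#2e8b57" stroke-width="2"/><polygon points="269,56 276,60 269,64" fill="#2e8b57"/>
<path d="M 287 78 A 8 8 0 0 1 303 78 Z" fill="#e69f00" stroke="black" stroke-width="1"/>
<polygon points="313,70 329,70 337,78 329,86 313,86" fill="red" stroke="black" stroke-width="1"/>
<text x="325" y="114" font-size="9" font-family="sans-serif" text-anchor="middle">RFP</text>
<path d="M 355 78 V 64 M 347 64 H 363" fill="none" stroke="#cc0000" stroke-width="2"/>
<circle cx="385" cy="78" r="7" fill="white" stroke="#707070" stroke-width="2"/>
<path d="M 85 52 V 48 H 265 V 52" fill="none" stroke="#2e8b57" stroke-width="1.5"/>
<polygon points="261,52 269,52 265,58" fill="#2e8b57"/>
<path d="M 205 52 V 36 H 265 V 52" fill="none" stroke="#2e8b57" stroke-width="1.5"/>
<polygon points="261,52 269,52 265,58" fill="#2e8b57"/>
</svg>
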