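<svg xmlns="http://www.w3.org/2000/svg" version="1.1" width="170" height="104" viewBox="0 0 170 104">
<line x1="0" y1="54" x2="170" y2="54" stroke="black" stroke-width="2"/>
<path d="M 17 54 V 36 H 29" fill="none" stroke="#2e8b57" stroke-width="2"/><polygon points="29,32 36,36 29,40" fill="#2e8b57"/>
<path d="M 47 54 A 8 8 0 0 1 63 54 Z" fill="#e69f00" stroke="black" stroke-width="1"/>
<polygon points="73,46 89,46 97,54 89,62 73,62" fill="#4169e1" stroke="black" stroke-width="1"/>
<path d="M 115 54 V 40 M 107 40 H 123" fill="none" stroke="#cc0000" stroke-width="2"/>
<circle cx="145" cy="54" r="7" fill="white" stroke="#707070" stroke-width="2"/>
</svg>
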