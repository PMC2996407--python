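<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">
  <xs:element name="matchrun">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="metadata">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="motif">
                <xs:complexType>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                  <xs:attribute name="source" type="xs:string" use="required"/>
                  <xs:attribute name="size" type="xs:positiveInteger" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="config">
                <xs:complexType>
                  <xs:simpleContent>
                    <xs:extension base="xs:string">
                      <xs:attribute name="hash" type="xs:string" use="required"/>
                    </xs:extension>
                  </xs:simpleContent>
                </xs:complexType>
              </xs:element>
              <xs:element name="targets">
                <xs:complexType>
                  <xs:attribute name="considered" type="xs:nonNegativeInteger" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="profile" minOccurs="0">
                <xs:complexType>
                  <xs:attribute name="n_matched" type="xs:nonNegativeInteger" use="required"/>
                  <xs:attribute name="n_missed" type="xs:nonNegativeInteger" use="required"/>
                  <xs:attribute name="bandwidth" type="xs:decimal" use="required"/>
                  <xs:attribute name="bandwidth_method" type="xs:string" use="required"/>
                  <xs:attribute name="w_match" type="xs:decimal" use="required"/>
                  <xs:attribute name="epsilon" type="xs:decimal" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="matches">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="match" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="pair" minOccurs="0" maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="point" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="chain" type="xs:string" use="required"/>
                        <xs:attribute name="seqnum" type="xs:integer" use="required"/>
                        <xs:attribute name="icode" type="xs:string" use="required"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="target" type="xs:string" use="required"/>
                  <xs:attribute name="ca_rmsd" type="xs:decimal" use="required"/>
                  <xs:attribute name="size" type="xs:positiveInteger" use="required"/>
                  <xs:attribute name="complete" type="xs:boolean" use="required"/>
                  <xs:attribute name="seed_key" type="xs:string" use="required"/>
                  <xs:attribute name="centroid_rmsd" type="xs:decimal"/>
                  <xs:attribute name="p_value" type="xs:double"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
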