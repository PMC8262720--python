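<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">
  <xs:element name="interaction_report">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="configuration">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="threshold" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="key" type="xs:string" use="required"/>
                  <xs:attribute name="value" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="mode" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="key" type="xs:string" use="required"/>
                  <xs:attribute name="value" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="hydrogenation">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="placement_failure" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="residue" type="xs:string" use="required"/>
                  <xs:attribute name="atom" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="added" type="xs:nonNegativeInteger" use="required"/>
            <xs:attribute name="failed" type="xs:nonNegativeInteger" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="binding_sites">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="binding_site" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="receptor_summary">
                      <xs:complexType>
                        <xs:attribute name="amino_acid" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="dna" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="rna" type="xs:nonNegativeInteger" use="required"/>
                        <xs:attribute name="other" type="xs:nonNegativeInteger" use="required"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="interaction_group" minOccurs="8" maxOccurs="8">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="interaction" minOccurs="0" maxOccurs="unbounded">
                            <xs:complexType>
                              <xs:attribute name="type" use="required">
                                <xs:simpleType>
                                  <xs:restriction base="xs:string">
                                    <xs:enumeration value="hydrophobic"/>
                                    <xs:enumeration value="hbond"/>
                                    <xs:enumeration value="water_bridge"/>
                                    <xs:enumeration value="salt_bridge"/>
                                    <xs:enumeration value="pistack"/>
                                    <xs:enumeration value="pication"/>
                                    <xs:enumeration value="halogen"/>
                                    <xs:enumeration value="metal"/>
                                  </xs:restriction>
                                </xs:simpleType>
                              </xs:attribute>
                              <xs:attribute name="rec_residue" type="xs:string" use="required"/>
                              <xs:attribute name="rec_chain" type="xs:string" use="required"/>
                              <xs:attribute name="receptor_is_nucleic" type="xs:boolean" use="required"/>
                              <xs:anyAttribute processContents="skip"/>
                            </xs:complexType>
                          </xs:element>
                        </xs:sequence>
                        <xs:attribute name="type" type="xs:string" use="required"/>
                        <xs:attribute name="count" type="xs:nonNegativeInteger" use="required"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                  <xs:attribute name="ligand_kind" type="xs:string" use="required"/>
                  <xs:attribute name="composite" type="xs:boolean" use="required"/>
                  <xs:attribute name="has_contacts" type="xs:boolean" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="count" type="xs:nonNegativeInteger" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="engine" type="xs:string" use="required"/>
      <xs:attribute name="version" type="xs:string" use="required"/>
      <xs:attribute name="input" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
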